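cbsa_id,mean_pm25
synthetic_cbsa_000,5.790167
synthetic_cbsa_001,5.908686
synthetic_cbsa_002,5.986827
synthetic_cbsa_003,6.049837
synthetic_cbsa_004,6.104427
synthetic_cbsa_005,6.153523
synthetic_cbsa_006,6.198702
synthetic_cbsa_007,6.240924
synthetic_cbsa_008,6.280823
synthetic_cbsa_009,6.318843
synthetic_cbsa_010,6.355308
synthetic_cbsa_011,6.390464
synthetic_cbsa_012,6.4245
synthetic_cbsa_013,6.457568
synthetic_cbsa_014,6.489791
synthetic_cbsa_015,6.521271
synthetic_cbsa_016,6.552091
synthetic_cbsa_017,6.582322
synthetic_cbsa_018,6.612026
synthetic_cbsa_019,6.641254
synthetic_cbsa_020,6.670053
synthetic_cbsa_021,6.698462
synthetic_cbsa_022,6.726515
synthetic_cbsa_023,6.754245
synthetic_cbsa_024,6.781679
synthetic_cbsa_025,6.808842
synthetic_cbsa_026,6.835756
synthetic_cbsa_027,6.862441
synthetic_cbsa_028,6.888917
synthetic_cbsa_029,6.915199
synthetic_cbsa_030,6.941303
synthetic_cbsa_031,6.967244
synthetic_cbsa_032,6.993033
synthetic_cbsa_033,7.018685
synthetic_cbsa_034,7.044209
synthetic_cbsa_035,7.069615
synthetic_cbsa_036,7.094915
synthetic_cbsa_037,7.120115
synthetic_cbsa_038,7.145226
synthetic_cbsa_039,7.170256
synthetic_cbsa_040,7.19521
synthetic_cbsa_041,7.220097
synthetic_cbsa_042,7.244924
synthetic_cbsa_043,7.269696
synthetic_cbsa_044,7.294419
synthetic_cbsa_045,7.3191
synthetic_cbsa_046,7.343743
synthetic_cbsa_047,7.368354
synthetic_cbsa_048,7.392938
synthetic_cbsa_049,7.417499
synthetic_cbsa_050,7.442043
synthetic_cbsa_051,7.466572
synthetic_cbsa_052,7.491093
synthetic_cbsa_053,7.515607
synthetic_cbsa_054,7.540121
synthetic_cbsa_055,7.564636
synthetic_cbsa_056,7.589157
synthetic_cbsa_057,7.613688
synthetic_cbsa_058,7.638231
synthetic_cbsa_059,7.662791
synthetic_cbsa_060,7.687369
synthetic_cbsa_061,7.711971
synthetic_cbsa_062,7.736597
synthetic_cbsa_063,7.761253
synthetic_cbsa_064,7.785939
synthetic_cbsa_065,7.81066
synthetic_cbsa_066,7.835418
synthetic_cbsa_067,7.860216
synthetic_cbsa_068,7.885057
synthetic_cbsa_069,7.909943
synthetic_cbsa_070,7.934876
synthetic_cbsa_071,7.95986
synthetic_cbsa_072,7.984898
synthetic_cbsa_073,8.00999
synthetic_cbsa_074,8.035141
synthetic_cbsa_075,8.060352
synthetic_cbsa_076,8.085626
synthetic_cbsa_077,8.110966
synthetic_cbsa_078,8.136373
synthetic_cbsa_079,8.16185
synthetic_cbsa_080,8.1874
synthetic_cbsa_081,8.213025
synthetic_cbsa_082,8.238727
synthetic_cbsa_083,8.264509
synthetic_cbsa_084,8.290373
synthetic_cbsa_085,8.316321
synthetic_cbsa_086,8.342356
synthetic_cbsa_087,8.36848
synthetic_cbsa_088,8.394695
synthetic_cbsa_089,8.421004
synthetic_cbsa_090,8.447409
synthetic_cbsa_091,8.473913
synthetic_cbsa_092,8.500517
synthetic_cbsa_093,8.527225
synthetic_cbsa_094,8.554039
synthetic_cbsa_095,8.58096
synthetic_cbsa_096,8.607992
synthetic_cbsa_097,8.635137
synthetic_cbsa_098,8.662398
synthetic_cbsa_099,8.689777
synthetic_cbsa_100,8.717276
synthetic_cbsa_101,8.744898
synthetic_cbsa_102,8.772646
synthetic_cbsa_103,8.800521
synthetic_cbsa_104,8.828528
synthetic_cbsa_105,8.856669
synthetic_cbsa_106,8.884945
synthetic_cbsa_107,8.913361
synthetic_cbsa_108,8.941918
synthetic_cbsa_109,8.97062
synthetic_cbsa_110,8.999469
synthetic_cbsa_111,9.028469
synthetic_cbsa_112,9.057621
synthetic_cbsa_113,9.08693
synthetic_cbsa_114,9.116399
synthetic_cbsa_115,9.146029
synthetic_cbsa_116,9.175825
synthetic_cbsa_117,9.20579
synthetic_cbsa_118,9.235927
synthetic_cbsa_119,9.266239
synthetic_cbsa_120,9.296729
synthetic_cbsa_121,9.327402
synthetic_cbsa_122,9.35826
synthetic_cbsa_123,9.389308
synthetic_cbsa_124,9.420548
synthetic_cbsa_125,9.451985
synthetic_cbsa_126,9.483623
synthetic_cbsa_127,9.515465
synthetic_cbsa_128,9.547515
synthetic_cbsa_129,9.579777
synthetic_cbsa_130,9.612256
synthetic_cbsa_131,9.644956
synthetic_cbsa_132,9.677882
synthetic_cbsa_133,9.711036
synthetic_cbsa_134,9.744426
synthetic_cbsa_135,9.778054
synthetic_cbsa_136,9.811926
synthetic_cbsa_137,9.846048
synthetic_cbsa_138,9.880423
synthetic_cbsa_139,9.915057
synthetic_cbsa_140,9.949956
synthetic_cbsa_141,9.985125
synthetic_cbsa_142,10.020569
synthetic_cbsa_143,10.056296
synthetic_cbsa_144,10.09231
synthetic_cbsa_145,10.128618
synthetic_cbsa_146,10.165226
synthetic_cbsa_147,10.202141
synthetic_cbsa_148,10.239369
synthetic_cbsa_149,10.276918
synthetic_cbsa_150,10.314795
synthetic_cbsa_151,10.353007
synthetic_cbsa_152,10.391562
synthetic_cbsa_153,10.430467
synthetic_cbsa_154,10.469732
synthetic_cbsa_155,10.509365
synthetic_cbsa_156,10.549373
synthetic_cbsa_157,10.589768
synthetic_cbsa_158,10.630557
synthetic_cbsa_159,10.671751
synthetic_cbsa_160,10.713359
synthetic_cbsa_161,10.755394
synthetic_cbsa_162,10.797864
synthetic_cbsa_163,10.840782
synthetic_cbsa_164,10.88416
synthetic_cbsa_165,10.928009
synthetic_cbsa_166,10.972343
synthetic_cbsa_167,11.017175
synthetic_cbsa_168,11.062518
synthetic_cbsa_169,11.108388
synthetic_cbsa_170,11.1548
synthetic_cbsa_171,11.201768
synthetic_cbsa_172,11.249311
synthetic_cbsa_173,11.297444
synthetic_cbsa_174,11.346187
synthetic_cbsa_175,11.395558
synthetic_cbsa_176,11.445577
synthetic_cbsa_177,11.496265
synthetic_cbsa_178,11.547644
synthetic_cbsa_179,11.599738
synthetic_cbsa_180,11.65257
synthetic_cbsa_181,11.706166
synthetic_cbsa_182,11.760554
synthetic_cbsa_183,11.815762
synthetic_cbsa_184,11.871821
synthetic_cbsa_185,11.928762
synthetic_cbsa_186,11.986621
synthetic_cbsa_187,12.045432
synthetic_cbsa_188,12.105235
synthetic_cbsa_189,12.166071
synthetic_cbsa_190,12.227984
synthetic_cbsa_191,12.29102
synthetic_cbsa_192,12.355231
synthetic_cbsa_193,12.420669
synthetic_cbsa_194,12.487392
synthetic_cbsa_195,12.555464
synthetic_cbsa_196,12.624952
synthetic_cbsa_197,12.695928
synthetic_cbsa_198,12.768471
synthetic_cbsa_199,12.842669
synthetic_cbsa_200,12.918613
synthetic_cbsa_201,12.996408
synthetic_cbsa_202,13.076166
synthetic_cbsa_203,13.158011
synthetic_cbsa_204,13.24208
synthetic_cbsa_205,13.328525
synthetic_cbsa_206,13.417516
synthetic_cbsa_207,13.509243
synthetic_cbsa_208,13.603919
synthetic_cbsa_209,13.701786
synthetic_cbsa_210,13.803119
synthetic_cbsa_211,13.908234
synthetic_cbsa_212,14.017494
synthetic_cbsa_213,14.131325
synthetic_cbsa_214,14.250225
synthetic_cbsa_215,14.374785
synthetic_cbsa_216,14.505718
synthetic_cbsa_217,14.643892
synthetic_cbsa_218,14.790383
synthetic_cbsa_219,14.946548
synthetic_cbsa_220,15.114143
synthetic_cbsa_221,15.295497
synthetic_cbsa_222,15.493814
synthetic_cbsa_223,15.713699
synthetic_cbsa_224,15.962167
synthetic_cbsa_225,16.250829
synthetic_cbsa_226,16.601443
synthetic_cbsa_227,17.064525
synthetic_cbsa_228,17.834204
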
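birth_year,sex,age,q
1930,M,60,0.01155
1930,M,61,0.01255598
1930,M,62,0.01364958
1930,M,63,0.01483843
1930,M,64,0.01613083
1930,M,65,0.01753579
1930,M,66,0.01906312
1930,M,67,0.02072348
1930,M,68,0.02252845
1930,M,69,0.02449064
1930,M,70,0.02662372
1930,M,71,0.02894259
1930,M,72,0.03146343
1930,M,73,0.03420383
1930,M,74,0.03718291
1930,M,75,0.04042147
1930,M,76,0.0439421
1930,M,77,0.04776936
1930,M,78,0.05192998
1930,M,79,0.05645297
1930,M,80,0.06136991
1940,M,60,0.011
1940,M,61,0.01195808
1940,M,62,0.0129996
1940,M,63,0.01413184
1940,M,64,0.01536269
1940,M,65,0.01670075
1940,M,66,0.01815535
1940,M,67,0.01973665
1940,M,68,0.02145567
1940,M,69,0.02332441
1940,M,70,0.02535592
1940,M,71,0.02756437
1940,M,72,0.02996517
1940,M,73,0.03257508
1940,M,74,0.0354123
1940,M,75,0.03849664
1940,M,76,0.04184962
1940,M,77,0.04549463
1940,M,78,0.04945712
1940,M,79,0.05376473
1940,M,80,0.05844753
1950,M,60,0.01045
1950,M,61,0.01136017
1950,M,62,0.01234962
1950,M,63,0.01342525
1950,M,64,0.01459456
1950,M,65,0.01586572
1950,M,66,0.01724759
1950,M,67,0.01874982
1950,M,68,0.02038289
1950,M,69,0.02215819
1950,M,70,0.02408813
1950,M,71,0.02618615
1950,M,72,0.02846691
1950,M,73,0.03094632
1950,M,74,0.03364168
1950,M,75,0.03657181
1950,M,76,0.03975713
1950,M,77,0.0432199
1950,M,78,0.04698426
1950,M,79,0.0510765
1950,M,80,0.05552515
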
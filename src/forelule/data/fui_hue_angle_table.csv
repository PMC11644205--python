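# 21-level Forel-Ule lookup table: upper hue-angle boundary of each level, degrees.
# Boundaries are midpoints between the hue angles of adjacent FU comparator classes
# (CIE 1931 2-degree observer); the FUI-1 entry is a nominal ceiling (angles above
# it clamp to level 1). Hue angle convention: atan2(y', x') in degrees on [0, 360).
fui,alpha_upper_deg
1,232.500
2,227.380
3,220.970
4,210.105
5,191.000
6,163.275
7,132.965
8,109.020
9,94.060
10,83.310
11,74.665
12,68.070
13,62.310
14,56.600
15,50.765
16,45.035
17,39.705
18,34.930
19,30.505
20,26.340
21,22.640
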
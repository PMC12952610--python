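origin,NW,N,NE,SW,S,SE,Sofia,Total
NW,829,946,693,434,1282,389,2233,6808
N,798,2028,1381,479,1972,747,2181,9585
NE,540,1334,2037,365,1571,839,1490,8175
SW,382,511,418,475,901,269,1575,4531
S,979,1821,1559,778,4609,1184,3315,14245
SE,306,708,848,234,1226,742,959,5024
Sofia,701,825,594,585,1383,389,552,5029
Total,4535,8172,7530,3350,12945,4559,12305,53397
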
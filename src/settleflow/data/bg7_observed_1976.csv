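origin,NW,N,NE,SW,S,SE,Sofia,Total
NW,1896,1042,411,539,1261,271,1673,7093
N,1175,4152,2764,292,1427,559,747,11116
NE,471,1524,4642,220,983,994,492,9326
SW,268,146,122,823,298,67,310,2034
S,854,1107,759,813,9766,2500,1039,16838
SE,110,249,502,103,919,1685,259,3827
Sofia,3154,1446,833,1987,2264,864,0,10548
Total,7928,9666,10033,4777,16918,6940,4520,60782
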
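score,stage_class,min_prop,strict,first_within_minute
1,C,0.10,False,10
2,C,0.10,False,
3,C,0.00,True,10
4,C,0.00,True,
5,B2/3,0.10,False,10
6,B2/3,0.10,False,
7,B2/3,0.00,True,10
8,B2/3,0.00,True,
9,B1,0.10,False,10
10,B1,0.10,False,
11,B1,0.00,True,10
12,B1,0.00,True,
13,A2A3,0.00,True,
14,any,0.00,False,
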
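icd_prefix,item_label
O01,1a
O02,1a
O00,1b
O08,1b
O03,1a
O030,1b
O031,1b
O032,1b
O033,1b
O035,1b
O036,1b
O037,1b
O038,1b
O04,1a
O040,1b
O041,1b
O042,1b
O043,1b
O045,1b
O046,1b
O047,1b
O048,1b
O05,1a
O050,1b
O051,1b
O052,1b
O053,1b
O055,1b
O056,1b
O057,1b
O058,1b
O06,1a
O060,1b
O061,1b
O062,1b
O063,1b
O065,1b
O066,1b
O067,1b
O068,1b
O07,1a
O070,1b
O071,1b
O072,1b
O073,1b
O075,1b
O076,1b
O077,1b
O078,1b
O13,2a
O14,2a
O15,2a
O16,2a
O10,2b
O11,2b
O20,3
O44,3
O45,3
O46,3
O67,3
O72,3
O85,4a
O23,4a
O411,4a
O753,4a
O86,4a
O91,4a
A41,4b
A,4b
B,4b
O21,5
O22,5
O25,5
O26,5
O27,5
O28,5
O29,5
O30,5
O31,5
O32,5
O33,5
O34,5
O35,5
O36,5
O37,5
O38,5
O39,5
O40,5
O41,5
O42,5
O43,5
O47,5
O48,5
O49,5
O50,5
O51,5
O52,5
O53,5
O54,5
O55,5
O56,5
O57,5
O58,5
O59,5
O60,5
O61,5
O62,5
O63,5
O64,5
O65,5
O66,5
O68,5
O69,5
O70,5
O71,5
O73,5
O74,5
O75,5
O244,7a
O24,7b
E10,7b
E11,7b
E12,7b
E13,7b
E14,7b
J18,8a
O995,8a
J,8a
K35,8b
O996,8b
K,8b
I26,8c
O994,8c
I,8c
O990,8d
D50,8d
D51,8d
D52,8d
D53,8d
D54,8d
D55,8d
D56,8d
D57,8d
D58,8d
D59,8d
D60,8d
D61,8d
D62,8d
D63,8d
D64,8d
N17,8e
O98,8e
O99,8e
C,8e
D,8e
E,8e
F,8e
G,8e
H,8e
L,8e
M,8e
N,8e
R,8e
R99,9
R95,9
R96,9
R98,9
O80,10
O81,10
O82,10
O83,10
O84,10
Z34,11
Z35,11
O09,11
S06,12
S,12
T,12
V,12
W,12
X,12
Y,12
Z99,13
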
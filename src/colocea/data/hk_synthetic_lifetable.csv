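age,qx
0,0.00051986482343158169
1,0.00052185696236617396
2,0.00052404763100211138
3,0.00052645661362327179
4,0.00052910566599129183
5,0.00053201871177999127
6,0.0005352220585751466
7,0.00053874463539183015
8,0.00054261825384838147
9,0.00054687789535368125
10,0.00055156202689621292
11,0.00055671294828174567
12,0.00056237717394846953
13,0.00056860585280094078
14,0.00057545522984270292
15,0.00058298715376814414
16,0.00059126963507905028
17,0.00060037745975383139
18,0.00061039286398700821
19,0.00062140627606865895
20,0.0006335171320742683
21,0.00064683477269156242
22,0.00066147942924266179
23,0.00067758330774803088
24,0.00069529178076011
25,0.00071476469764808481
26,0.00073617782507195972
27,0.00075972443053873295
28,0.00078561702319857041
29,0.00081408926743498089
30,0.00084539808632000391
31,0.00087982597368485571
32,0.00091768353538190794
33,0.00095931228232259969
34,0.0010050877000745695
35,0.0010554226222028174
36,0.001110770937175154
37,0.0011716316615241196
38,0.0012385534151069244
39,0.0013121393377338864
40,0.0013930524901862862
41,0.0014820217867261842
42,0.0015798485106562898
43,0.0016874134693267706
44,0.0018056848502522316
45,0.0019357268457194099
46,0.0020787091194580665
47,0.0022359171956565227
48,0.0024087638578430548
49,0.0025988016529655544
50,0.0028077366043959273
51,0.0030374432465920531
52,0.0032899811037764293
53,0.0035676127452453077
54,0.0038728235607956574
55,0.0042083434112379914
56,0.0045771703210006898
57,0.0049825963923758598
58,0.0054282361339068608
59,0.0059180574086505899
60,0.0064564152213839598
61,0.0070480885770317636
62,0.0076983206553671302
63,0.0084128625589886541
64,0.0091980209022063386
65,0.010060709517150435
66,0.011008505559374604
67,0.012049710297480809
68,0.013193414868664877
69,0.014449571273101314
70,0.015829068862978302
71,0.017343816554605707
72,0.019006830951748932
73,0.02083233051208111
74,0.022835835812677452
75,0.025034275870396083
76,0.027446100343594959
77,0.030091397276844956
78,0.032992015843007261
79,0.036171693279076544
80,0.039656184894152569
81,0.043473395639188617
82,0.047653511256866454
83,0.052229126462973285
84,0.05723536693382214
85,0.062710001072621924
86,0.06869353658600974
87,0.075229295805429697
88,0.082363462423453937
89,0.090145090872401967
90,0.098626067946940843
91,0.10786101446713647
92,0.11790711280911759
93,0.1288238440294539
94,0.14067261613203941
95,0.15351626285890263
96,0.16741839035497652
97,0.18244254733788368
98,0.19865119323569747
99,0.21610443845134919
100,1
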
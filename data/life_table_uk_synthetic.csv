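age,qx
0,0.00021930000000000002
1,0.00022127654082217222
2,0.00022345550203925181
3,0.00022585761381568314
4,0.00022850572932193501
5,0.00023142504215460836
6,0.00023464332602285008
7,0.00023819119898139845
8,0.0002421024147241153
9,0.00024641418370930897
10,0.00025116752717196434
11,0.00025640766739087585
12,0.00026218445792360008
13,0.00026855285790238994
14,0.00027557345490345956
15,0.00028331304136404385
16,0.00029184525003116059
17,0.00030125125448759587
18,0.00031162054141976577
19,0.00032305176197464292
20,0.00033565367030537337
21,0.00034954615823470285
22,0.00036486139587977602
23,0.0003817450890899661
24,0.00040035786566072458
25,0.00042087680351159064
26,0.00044349711536711224
27,0.00046843400596836978
28,0.00049592471948420888
29,0.00052623079660080966
30,0.00055964056276305082
31,0.0005964718712402606
32,0.00063707512711328525
33,0.00068183662095243087
34,0.00073118220390217101
35,0.00078558133913657704
36,0.00084555156823013704
37,0.00091166343493605088
38,0.00098454591321576047
39,0.0010648923911608028
40,0.0011534672677367328
41,0.0012511132251090973
42,0.0013587592457387962
43,0.0014774294505197391
44,0.0016082528420429134
45,0.0017524740456821794
46,0.0019114651506901407
47,0.0020867387639577129
48,0.002279962400628029
49,0.0024929743484738624
50,0.0027278011569687993
51,0.0029866769174394176
52,0.0032720645177256352
53,0.0035866790735614622
54,0.0039335137595972415
55,0.0043158682858141055
56,0.0047373802902491045
57,0.0052020599466945389
58,0.0057143281166217013
59,0.0062790584082981112
60,0.0069016235432395809
61,0.007587946471117467
62,0.0083445567194172961
63,0.0091786525139470956
64,0.010098169261196603
65,0.011111855044073549
66,0.012229353849267176
67,0.013461297318045974
68,0.014819405893386923
69,0.016316600325728063
70,0.017967124598185849
71,0.019786681440721293
72,0.021792581722507209
73,0.024003909143783107
74,0.026441701794040356
75,0.029129152303842953
76,0.032091828494484533
77,0.035357916624695056
78,0.038958489548593309
79,0.042927802336081865
80,0.047303618168152865
81,0.052127567607601837
82,0.057445544663173434
83,0.063308143415206866
84,0.069771139356743214
85,0.076896020029470352
86,0.084750570002858155
87,0.093409515761851775
88,0.10295523663844261
89,0.11347854855076624
90,0.12507956800605144
91,0.13786866458735661
92,0.15196751098584585
93,0.16751024056838429
94,0.18464472349329941
95,0.20353397351499733
96,0.224357698861467
97,0.24731401193938782
98,0.27262131413259749
99,0.30052037362549255
100,0.33127661601931602
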
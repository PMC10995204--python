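age_start,age_width,sex,residence,division,mx
0,1.0,male,total,total,0.02376360469
1,4.0,male,total,total,0.001774230202
5,5.0,male,total,total,0.001800745669
10,5.0,male,total,total,0.001846800112
15,5.0,male,total,total,0.001920856309
20,5.0,male,total,total,0.002039939726
25,5.0,male,total,total,0.00223142755
30,5.0,male,total,total,0.002539342691
35,5.0,male,total,total,0.003034474609
40,5.0,male,total,total,0.003830653763
45,5.0,male,total,total,0.005110921145
50,5.0,male,total,total,0.007169609273
55,5.0,male,total,total,0.01048000901
60,5.0,male,total,total,0.01580317879
65,5.0,male,total,total,0.02436291137
70,5.0,male,total,total,0.03812708288
75,5.0,male,total,total,0.06026006609
80,open,male,total,total,0.1357982844
0,1.0,female,total,total,0.0233188696
1,4.0,female,total,total,0.001326815629
5,5.0,female,total,total,0.001346644588
10,5.0,female,total,total,0.001381085301
15,5.0,female,total,total,0.001436466457
20,5.0,female,total,total,0.001525520143
25,5.0,female,total,total,0.001668719733
30,5.0,female,total,total,0.001898986708
35,5.0,female,total,total,0.002269259273
40,5.0,female,total,total,0.002864662814
45,5.0,female,total,total,0.003822080161
50,5.0,female,total,total,0.005361620848
55,5.0,female,total,total,0.00783722413
60,5.0,female,total,total,0.01181802936
65,5.0,female,total,total,0.01821922067
70,5.0,female,total,total,0.0285124272
75,5.0,female,total,total,0.04506404942
80,open,female,total,total,0.1131870716
0,1.0,total,total,total,0.0235335693
1,4.0,total,total,total,0.001542808871
5,5.0,total,total,total,0.0015658658
10,5.0,total,total,total,0.001605913141
15,5.0,total,total,total,0.001670309834
20,5.0,total,total,total,0.001773860631
25,5.0,total,total,total,0.001940371783
30,5.0,total,total,total,0.002208124079
35,5.0,total,total,total,0.002638673573
40,5.0,total,total,total,0.003331003272
45,5.0,total,total,total,0.004444279257
50,5.0,total,total,total,0.006234442846
55,5.0,total,total,total,0.009113051314
60,5.0,total,total,total,0.0137418946
65,5.0,total,total,total,0.02118514032
70,5.0,total,total,total,0.03315398511
75,5.0,total,total,total,0.05240005747
80,open,total,total,total,0.1242307801
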
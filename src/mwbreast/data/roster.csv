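breast_index,patient_index,age,side,breast_type,inclusion_position,inclusion_dimension,final_assessment
1,1,48,L,WF,Upper Zone,Not Available,Benign
2,1,48,R,NF,–,–,–
3,2,65,L,WF,Upper Zone,Not Available,Benign
4,2,65,R,NF,–,–,–
5,3,65,R,NF,–,–,–
6,4,57,R,NF,–,–,Benign
7,4,57,L,NF,–,–,–
8,5,40,L,WF,More Areas,Not Available,Benign
9,5,40,R,WF,Upper Zone,9 Mm,Benign
10,6,52,L,WF,Upper Zone,Not Available,Malignant
11,6,52,R,NF,–,–,–
12,7,36,L,NF,–,–,–
13,8,47,L,WF,More Areas,Multi Inclusions of 1mm,Benign
14,9,54,R,NF,–,–,–
15,9,54,L,NF,–,–,–
16,10,55,R,WF,Upper Zone,"1, 6 Mm",Benign
17,10,55,L,WF,Upper Zone,"3, 8 Mm",Benign
18,11,51,L,WF,Upper Zone,Not Available,Benign
19,12,54,R,WF,Upper Zone,Not Available,Benign
20,12,54,L,NF,–,–,–
21,13,77,R,WF,Upper Zone,17 Mm,Malignant
22,14,61,R,WF,Upper Zone,15 Mm,Malignant
23,14,61,L,WF,Upper Zone,Not Available,Benign
24,15,50,R,NF,–,–,–
25,15,50,L,WF,Lower Zone,10 Mm,Benign
26,16,67,L,WF,Lower Zone,"5, 5 Mm",Malignant
27,16,67,R,NF,–,–,–
28,17,49,L,WF,Upper Zone,Not Available,Benign
29,17,49,R,NF,–,–,–
30,18,70,L,WF,Upper Zone,Not Available,Malignant
31,19,42,L,WF,Upper Zone,7 Mm,Benign
32,20,67,L,WF,Upper Zone,10 Mm,Benign
33,20,67,R,NF,–,–,–
34,21,56,R,WF,Upper Zone,31 Mm,Malignant
35,22,43,R,WF,Upper Zone,12 Mm,Benign
36,22,43,L,NF,–,–,–
37,23,51,L,WF,Lower Zone,Not Available,Benign
38,23,51,R,NF,–,–,–
39,24,59,L,WF,Upper Zone,11 Mm,Malignant
40,24,59,R,NF,–,–,–
41,25,40,L,WF,Lower Zone,32 Mm,Benign
42,25,40,R,NF,–,–,–
43,26,35,R,WF,Upper Zone,7 Mm,Benign
44,26,35,L,NF,–,–,–
45,27,37,L,WF,Lower Zone,25 Mm,Benign
46,27,37,R,NF,–,–,–
47,28,43,R,WF,Upper Zone,Not Available,Malignant
48,28,43,L,NF,–,–,–
49,29,54,R,WF,Upper Zone,18 Mm,Benign
50,30,49,L,WF,Upper Zone,16 Mm,Benign
51,30,49,R,NF,–,–,–
52,31,56,L,WF,Upper Zone,27 Mm,Malignant
53,31,56,R,NF,–,–,–
54,32,63,L,WF,Upper Zone,6 Mm,Malignant
55,32,63,R,NF,–,–,–
56,33,55,R,WF,Upper Zone,23 Mm,Malignant
57,33,55,L,WF,–,Not Available,Benign
58,34,64,R,WF,Upper Zone,Not Available,Benign
59,34,64,L,NF,–,–,–
60,35,37,R,WF,Lower Zone,15.4mm,Benign
61,35,37,L,WF,Not Available,Not Available,Benign
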
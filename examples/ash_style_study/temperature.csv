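age_ma,temperature_c
0,2.278729592
0.25,-1.071499004
0.5,1.837311449
0.75,1.298746059
1,2.25610835
1.25,1.686607142
1.5,2.779081039
1.75,1.605553965
2,1.305306056
2.25,2.156339445
2.5,2.135808136
2.75,1.666879116
3,1.826887325
3.25,2.566108475
3.5,2.618021196
3.75,1.841746039
4,1.992600393
4.25,1.047746727
4.5,3.550445227
4.75,2.280496385
5,3.436094201
5.25,2.854725916
5.5,3.985773942
5.75,3.763476983
6,2.972808908
6.25,3.849034394
6.5,2.209913535
6.75,3.8185327
7,1.963703461
7.25,3.323598791
7.5,3.912080195
7.75,3.406542499
8,3.076337085
8.25,2.852774635
8.5,3.260039989
8.75,4.319120933
9,4.290254279
9.25,3.566507976
9.5,2.96113029
9.75,4.388464736
10,2.985088244
10.25,3.7117349
10.5,3.652286803
10.75,4.770285647
11,4.498498152
11.25,4.739964979
11.5,4.690685537
11.75,4.108782252
12,5.041499855
12.25,5.738722258
12.5,4.807593463
12.75,5.360182792
13,4.911867765
13.25,5.969988799
13.5,5.966645657
13.75,6.36307363
14,6.243896097
14.25,7.398002717
14.5,6.247194595
14.75,6.516083746
15,6.585698012
15.25,7.404946619
15.5,6.518865265
15.75,6.480645336
16,7.41832329
16.25,7.699830677
16.5,7.265682406
16.75,4.962736602
17,6.150639103
17.25,6.044011909
17.5,5.927469447
17.75,6.464562646
18,7.999552991
18.25,6.489366467
18.5,6.16700614
18.75,7.14826683
19,6.684783847
19.25,6.698113154
19.5,6.110237212
19.75,6.567128691
20,6.849630571
20.25,5.184812669
20.5,5.372842968
20.75,7.236465118
21,7.044648657
21.25,6.07715848
21.5,5.694948176
21.75,6.256480998
22,5.52807976
22.25,6.102841197
22.5,7.473952115
22.75,6.387904836
23,7.089129178
23.25,6.09416563
23.5,6.485863621
23.75,7.1746268
24,5.246661892
24.25,5.915856313
24.5,6.026534686
24.75,6.311023189
25,7.178475797
25.25,6.548050721
25.5,4.997087926
25.75,5.833046844
26,5.374449609
26.25,5.323333746
26.5,7.350712734
26.75,5.155920521
27,6.032143289
27.25,5.332684771
27.5,6.402686658
27.75,6.014258934
28,5.822532736
28.25,5.646683002
28.5,6.463068508
28.75,4.981143414
29,5.091143172
29.25,4.785042434
29.5,6.467515822
29.75,5.294503534
30,4.740486127
30.25,5.139981953
30.5,7.149752999
30.75,5.291435598
31,5.928347752
31.25,5.625627279
31.5,5.257998369
31.75,4.748439867
32,4.965993332
32.25,4.918549976
32.5,3.586840011
32.75,6.913092516
33,5.714052047
33.25,5.114733888
33.5,4.857655603
33.75,5.697248933
34,8.164735201
34.25,8.3778215
34.5,8.887214929
34.75,7.623580969
35,8.90286461
35.25,10.08124529
35.5,8.521397726
35.75,9.327209843
36,8.835078374
36.25,9.627081654
36.5,9.643748881
36.75,8.982807632
37,8.59104882
37.25,9.226589982
37.5,9.098203838
37.75,8.679536652
38,9.474707607
38.25,9.500901865
38.5,8.619060687
38.75,9.20644123
39,11.37238386
39.25,9.942473796
39.5,9.482238621
39.75,11.21465421
40,9.181217761
40.25,7.866202117
40.5,8.36514095
40.75,8.73634229
41,10.08203854
41.25,10.68344941
41.5,8.580866833
41.75,10.9820706
42,9.440583092
42.25,10.57950439
42.5,10.82474372
42.75,10.90263088
43,10.70528296
43.25,10.91969686
43.5,10.1021259
43.75,11.19475182
44,11.78575666
44.25,11.84835584
44.5,13.12899703
44.75,12.15826278
45,12.00849915
45.25,12.76445041
45.5,11.86879635
45.75,10.89708595
46,10.3320981
46.25,12.89359964
46.5,12.49762194
46.75,12.79310787
47,12.06698757
47.25,12.64138058
47.5,13.81766712
47.75,12.83438394
48,11.91913693
48.25,12.4979852
48.5,13.86957743
48.75,12.23702725
49,11.29299938
49.25,11.59423137
49.5,12.36274273
49.75,13.95957547
50,13.56192424
50.25,12.90740601
50.5,12.47540443
50.75,13.23270748
51,13.13828306
51.25,12.79275114
51.5,12.9533221
51.75,12.52827276
52,14.26225536
52.25,11.26501604
52.5,12.9292822
52.75,12.0555411
53,13.18206151
53.25,12.44480066
53.5,12.78746501
53.75,12.82524237
54,12.51872837
54.25,12.99060332
54.5,11.24471557
54.75,12.80681424
55,11.90924029
55.25,12.25082606
55.5,12.99582336
55.75,12.61520979
56,13.13873438
56.25,10.09646072
56.5,10.92463284
56.75,12.19054237
57,10.64602531
57.25,11.23156003
57.5,12.4767631
57.75,11.81541499
58,10.45141193
58.25,11.36453951
58.5,11.42046035
58.75,10.93778847
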
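label_id,name,volume_mm3,is_hub,community
1,ctx-lh-bankssts,4084.9,0,0
2,ctx-lh-caudalanteriorcingulate,5494.9,0,0
3,ctx-lh-caudalmiddlefrontal,6618.3,0,0
4,ctx-lh-cuneus,6783.4,0,0
5,ctx-lh-entorhinal,9199.7,0,0
6,ctx-lh-fusiform,8396.6,0,0
7,ctx-lh-inferiorparietal,4781.1,0,0
8,ctx-lh-inferiortemporal,13583.1,0,0
9,ctx-lh-isthmuscingulate,8363.7,0,0
10,ctx-lh-lateraloccipital,6003.4,0,0
11,ctx-lh-lateralorbitofrontal,5930.8,0,0
12,ctx-lh-lingual,9151.0,0,0
13,ctx-lh-medialorbitofrontal,10978.9,0,0
14,ctx-lh-middletemporal,11703.6,0,0
15,ctx-lh-parahippocampal,18838.2,0,0
16,ctx-lh-paracentral,2324.7,0,0
17,ctx-lh-parsopercularis,12286.8,0,0
18,ctx-lh-parsorbitalis,10215.6,0,0
19,ctx-lh-parstriangularis,6370.7,0,0
20,ctx-lh-pericalcarine,7737.5,0,0
21,ctx-lh-postcentral,7409.3,0,0
22,ctx-lh-posteriorcingulate,4355.6,0,0
23,ctx-lh-precentral,3519.2,0,0
24,ctx-lh-precuneus,5993.7,0,0
25,ctx-lh-rostralanteriorcingulate,4763.5,0,0
26,ctx-lh-rostralmiddlefrontal,4103.6,0,0
27,ctx-lh-superiorfrontal,8122.7,0,0
28,ctx-lh-superiorparietal,4468.5,0,0
29,ctx-lh-superiortemporal,10776.6,0,0
30,ctx-lh-supramarginal,5052.2,0,0
31,ctx-lh-temporalpole,3095.4,0,0
32,ctx-lh-transversetemporal,5117.1,0,0
33,ctx-lh-insula,4702.0,0,0
34,ctx-lh-frontalpole,11409.4,0,0
35,ctx-rh-bankssts,13530.0,0,1
36,ctx-rh-caudalanteriorcingulate,4988.4,0,1
37,ctx-rh-caudalmiddlefrontal,8732.5,0,1
38,ctx-rh-cuneus,4628.2,0,1
39,ctx-rh-entorhinal,8688.0,0,1
40,ctx-rh-fusiform,15247.8,0,1
41,ctx-rh-inferiorparietal,9200.8,0,1
42,ctx-rh-inferiortemporal,8975.8,0,1
43,ctx-rh-isthmuscingulate,7164.6,0,1
44,ctx-rh-lateraloccipital,5121.1,0,1
45,ctx-rh-lateralorbitofrontal,7044.5,0,1
46,ctx-rh-lingual,6510.5,0,1
47,ctx-rh-medialorbitofrontal,9346.0,0,1
48,ctx-rh-middletemporal,3367.0,0,1
49,ctx-rh-parahippocampal,8162.2,0,1
50,ctx-rh-paracentral,8918.9,0,1
51,ctx-rh-parsopercularis,7501.9,0,1
52,ctx-rh-parsorbitalis,9442.2,0,1
53,ctx-rh-parstriangularis,10938.3,0,1
54,ctx-rh-pericalcarine,14191.2,0,1
55,ctx-rh-postcentral,5650.3,0,1
56,ctx-rh-posteriorcingulate,5529.3,0,1
57,ctx-rh-precentral,4375.0,0,1
58,ctx-rh-precuneus,4939.2,0,1
59,ctx-rh-rostralanteriorcingulate,5382.4,0,1
60,ctx-rh-rostralmiddlefrontal,6979.1,0,1
61,ctx-rh-superiorfrontal,2842.9,0,1
62,ctx-rh-superiorparietal,13278.9,0,1
63,ctx-rh-superiortemporal,3893.5,0,1
64,ctx-rh-supramarginal,5350.4,0,1
65,ctx-rh-temporalpole,3815.6,0,1
66,ctx-rh-transversetemporal,8830.4,0,1
67,ctx-rh-insula,9988.6,0,1
68,ctx-rh-frontalpole,5436.7,0,1
69,Left-Thalamus-Proper,7600.0,0,2
70,Left-Caudate,3600.0,0,2
71,Left-Putamen,5100.0,0,2
72,Left-Pallidum,1800.0,0,2
73,Left-Hippocampus,4200.0,0,2
74,Left-Amygdala,1600.0,0,2
75,Left-Accumbens-area,600.0,0,2
76,Left-Cerebellum-Cortex,52000.0,0,2
77,Right-Thalamus-Proper,7600.0,0,2
78,Right-Caudate,3600.0,0,2
79,Right-Putamen,5100.0,0,2
80,Right-Pallidum,1800.0,0,2
81,Right-Hippocampus,4200.0,0,2
82,Right-Amygdala,1600.0,0,2
83,Right-Accumbens-area,600.0,0,2
84,Right-Cerebellum-Cortex,52000.0,0,2
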
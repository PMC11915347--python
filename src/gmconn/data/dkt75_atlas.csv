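roi_id,name,hemisphere,lobe,is_cortical,homotopic_partner,system_tags
0,caudal-anterior-cingulate-L,L,cingulate,1,31,
1,caudal-middle-frontal-L,L,frontal,1,32,
2,cuneus-L,L,occipital,1,33,VIS
3,entorhinal-L,L,temporal,1,34,
4,fusiform-L,L,temporal,1,35,
5,inferior-parietal-L,L,parietal,1,36,
6,inferior-temporal-L,L,temporal,1,37,
7,isthmus-cingulate-L,L,cingulate,1,38,
8,lateral-occipital-L,L,occipital,1,39,VIS
9,lateral-orbitofrontal-L,L,frontal,1,40,
10,lingual-L,L,occipital,1,41,
11,medial-orbitofrontal-L,L,frontal,1,42,
12,middle-temporal-L,L,temporal,1,43,
13,parahippocampal-L,L,temporal,1,44,
14,paracentral-L,L,frontal,1,45,SM
15,pars-opercularis-L,L,frontal,1,46,
16,pars-orbitalis-L,L,frontal,1,47,
17,pars-triangularis-L,L,frontal,1,48,
18,pericalcarine-L,L,occipital,1,49,VIS
19,postcentral-L,L,parietal,1,50,SM
20,posterior-cingulate-L,L,cingulate,1,51,
21,precentral-L,L,frontal,1,52,SM
22,precuneus-L,L,parietal,1,53,
23,rostral-anterior-cingulate-L,L,cingulate,1,54,
24,rostral-middle-frontal-L,L,frontal,1,55,
25,superior-frontal-L,L,frontal,1,56,
26,superior-parietal-L,L,parietal,1,57,
27,superior-temporal-L,L,temporal,1,58,
28,supramarginal-L,L,parietal,1,59,
29,transverse-temporal-L,L,temporal,1,60,
30,insula-L,L,insular,1,61,
31,caudal-anterior-cingulate-R,R,cingulate,1,0,
32,caudal-middle-frontal-R,R,frontal,1,1,
33,cuneus-R,R,occipital,1,2,VIS
34,entorhinal-R,R,temporal,1,3,
35,fusiform-R,R,temporal,1,4,
36,inferior-parietal-R,R,parietal,1,5,
37,inferior-temporal-R,R,temporal,1,6,
38,isthmus-cingulate-R,R,cingulate,1,7,
39,lateral-occipital-R,R,occipital,1,8,VIS
40,lateral-orbitofrontal-R,R,frontal,1,9,
41,lingual-R,R,occipital,1,10,
42,medial-orbitofrontal-R,R,frontal,1,11,
43,middle-temporal-R,R,temporal,1,12,
44,parahippocampal-R,R,temporal,1,13,
45,paracentral-R,R,frontal,1,14,SM
46,pars-opercularis-R,R,frontal,1,15,
47,pars-orbitalis-R,R,frontal,1,16,
48,pars-triangularis-R,R,frontal,1,17,
49,pericalcarine-R,R,occipital,1,18,VIS
50,postcentral-R,R,parietal,1,19,SM
51,posterior-cingulate-R,R,cingulate,1,20,
52,precentral-R,R,frontal,1,21,SM
53,precuneus-R,R,parietal,1,22,
54,rostral-anterior-cingulate-R,R,cingulate,1,23,
55,rostral-middle-frontal-R,R,frontal,1,24,
56,superior-frontal-R,R,frontal,1,25,
57,superior-parietal-R,R,parietal,1,26,
58,superior-temporal-R,R,temporal,1,27,
59,supramarginal-R,R,parietal,1,28,
60,transverse-temporal-R,R,temporal,1,29,
61,insula-R,R,insular,1,30,
62,brainstem,medial,subcortical,0,,
63,thalamus-L,L,subcortical,0,64,thalamus
64,thalamus-R,R,subcortical,0,63,thalamus
65,caudate-L,L,subcortical,0,66,
66,caudate-R,R,subcortical,0,65,
67,lenticular-L,L,subcortical,0,68,
68,lenticular-R,R,subcortical,0,67,
69,amygdala-L,L,subcortical,0,70,
70,amygdala-R,R,subcortical,0,69,
71,hippocampus-L,L,subcortical,0,72,
72,hippocampus-R,R,subcortical,0,71,
73,cerebellum-L,L,subcortical,0,74,
74,cerebellum-R,R,subcortical,0,73,
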
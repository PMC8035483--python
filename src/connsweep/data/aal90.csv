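index,name,abbreviation,class,dmn
0,"Precentral gyrus, left",PreCG.L,cortical,0
1,"Precentral gyrus, right",PreCG.R,cortical,0
2,"Superior frontal gyrus, dorsolateral, left",SFGdor.L,cortical,0
3,"Superior frontal gyrus, dorsolateral, right",SFGdor.R,cortical,0
4,"Superior frontal gyrus, orbital part, left",ORBsup.L,cortical,0
5,"Superior frontal gyrus, orbital part, right",ORBsup.R,cortical,0
6,"Middle frontal gyrus, left",MFG.L,cortical,0
7,"Middle frontal gyrus, right",MFG.R,cortical,0
8,"Middle frontal gyrus, orbital part, left",ORBmid.L,cortical,0
9,"Middle frontal gyrus, orbital part, right",ORBmid.R,cortical,0
10,"Inferior frontal gyrus, opercular part, left",IFGoperc.L,cortical,0
11,"Inferior frontal gyrus, opercular part, right",IFGoperc.R,cortical,0
12,"Inferior frontal gyrus, triangular part, left",IFGtriang.L,cortical,0
13,"Inferior frontal gyrus, triangular part, right",IFGtriang.R,cortical,0
14,"Inferior frontal gyrus, orbital part, left",ORBinf.L,cortical,0
15,"Inferior frontal gyrus, orbital part, right",ORBinf.R,cortical,0
16,"Rolandic operculum, left",ROL.L,cortical,0
17,"Rolandic operculum, right",ROL.R,cortical,0
18,"Supplementary motor area, left",SMA.L,cortical,0
19,"Supplementary motor area, right",SMA.R,cortical,0
20,"Olfactory cortex, left",OLF.L,cortical,0
21,"Olfactory cortex, right",OLF.R,cortical,0
22,"Superior frontal gyrus, medial, left",SFGmed.L,cortical,1
23,"Superior frontal gyrus, medial, right",SFGmed.R,cortical,1
24,"Superior frontal gyrus, medial orbital, left",ORBsupmed.L,cortical,0
25,"Superior frontal gyrus, medial orbital, right",ORBsupmed.R,cortical,0
26,"Gyrus rectus, left",REC.L,cortical,0
27,"Gyrus rectus, right",REC.R,cortical,0
28,"Insula, left",INS.L,cortical,0
29,"Insula, right",INS.R,cortical,0
30,"Anterior cingulate and paracingulate gyri, left",ACG.L,cortical,0
31,"Anterior cingulate and paracingulate gyri, right",ACG.R,cortical,0
32,"Median cingulate and paracingulate gyri, left",DCG.L,cortical,0
33,"Median cingulate and paracingulate gyri, right",DCG.R,cortical,0
34,"Posterior cingulate gyrus, left",PCG.L,cortical,1
35,"Posterior cingulate gyrus, right",PCG.R,cortical,0
36,"Hippocampus, left",HIP.L,subcortical,0
37,"Hippocampus, right",HIP.R,subcortical,1
38,"Parahippocampal gyrus, left",PHG.L,cortical,0
39,"Parahippocampal gyrus, right",PHG.R,cortical,0
40,"Amygdala, left",AMYG.L,subcortical,0
41,"Amygdala, right",AMYG.R,subcortical,1
42,"Calcarine fissure and surrounding cortex, left",CAL.L,cortical,0
43,"Calcarine fissure and surrounding cortex, right",CAL.R,cortical,0
44,"Cuneus, left",CUN.L,cortical,0
45,"Cuneus, right",CUN.R,cortical,0
46,"Lingual gyrus, left",LING.L,cortical,0
47,"Lingual gyrus, right",LING.R,cortical,0
48,"Superior occipital gyrus, left",SOG.L,cortical,0
49,"Superior occipital gyrus, right",SOG.R,cortical,0
50,"Middle occipital gyrus, left",MOG.L,cortical,0
51,"Middle occipital gyrus, right",MOG.R,cortical,0
52,"Inferior occipital gyrus, left",IOG.L,cortical,0
53,"Inferior occipital gyrus, right",IOG.R,cortical,0
54,"Fusiform gyrus, left",FFG.L,cortical,0
55,"Fusiform gyrus, right",FFG.R,cortical,0
56,"Postcentral gyrus, left",PoCG.L,cortical,0
57,"Postcentral gyrus, right",PoCG.R,cortical,0
58,"Superior parietal gyrus, left",SPG.L,cortical,0
59,"Superior parietal gyrus, right",SPG.R,cortical,0
60,"Inferior parietal, supramarginal and angular gyri, left",IPL.L,cortical,0
61,"Inferior parietal, supramarginal and angular gyri, right",IPL.R,cortical,0
62,"Supramarginal gyrus, left",SMG.L,cortical,0
63,"Supramarginal gyrus, right",SMG.R,cortical,0
64,"Angular gyrus, left",ANG.L,cortical,1
65,"Angular gyrus, right",ANG.R,cortical,0
66,"Precuneus, left",PCUN.L,cortical,0
67,"Precuneus, right",PCUN.R,cortical,1
68,"Paracentral lobule, left",PCL.L,cortical,0
69,"Paracentral lobule, right",PCL.R,cortical,0
70,"Caudate nucleus, left",CAU.L,subcortical,0
71,"Caudate nucleus, right",CAU.R,subcortical,0
72,"Lenticular nucleus, putamen, left",PUT.L,subcortical,0
73,"Lenticular nucleus, putamen, right",PUT.R,subcortical,0
74,"Lenticular nucleus, pallidum, left",PAL.L,subcortical,0
75,"Lenticular nucleus, pallidum, right",PAL.R,subcortical,0
76,"Thalamus, left",THA.L,subcortical,0
77,"Thalamus, right",THA.R,subcortical,0
78,"Heschl gyrus, left",HES.L,cortical,0
79,"Heschl gyrus, right",HES.R,cortical,0
80,"Superior temporal gyrus, left",STG.L,cortical,0
81,"Superior temporal gyrus, right",STG.R,cortical,0
82,"Temporal pole: superior temporal gyrus, left",TPOsup.L,cortical,0
83,"Temporal pole: superior temporal gyrus, right",TPOsup.R,cortical,0
84,"Middle temporal gyrus, left",MTG.L,cortical,0
85,"Middle temporal gyrus, right",MTG.R,cortical,0
86,"Temporal pole: middle temporal gyrus, left",TPOmid.L,cortical,0
87,"Temporal pole: middle temporal gyrus, right",TPOmid.R,cortical,0
88,"Inferior temporal gyrus, left",ITG.L,cortical,0
89,"Inferior temporal gyrus, right",ITG.R,cortical,0
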
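region,abbreviation,side,x,y,z
Lentiform nucleus,LN,Left,-22,7,-5
Lentiform nucleus,LN,Right,23,10,1
Inferior parietal lobule,IPL,Left,-42,-55,45
Inferior parietal lobule,IPL,Right,44,-53,47
Parahippocampal gyrus,PHG,Left,-26,-40,-8
Parahippocampal gyrus,PHG,Right,27,-37,-13
Middle frontal gyrus,MFG,Left,-35,20,51
Middle frontal gyrus,MFG,Left,-42,38,21
Middle frontal gyrus,MFG,Left,-34,55,4
Middle frontal gyrus,MFG,Left,-28,52,21
Middle frontal gyrus,MFG,Left,-32,-1,54
Middle frontal gyrus,MFG,Right,34,38,-12
Middle frontal gyrus,MFG,Right,19,-8,64
Middle frontal gyrus,MFG,Right,23,33,48
Middle frontal gyrus,MFG,Right,42,0,47
Middle frontal gyrus,MFG,Right,29,-5,54
Inferior frontal gyrus,IFG,Left,-46,31,-13
Inferior frontal gyrus,IFG,Right,48,22,10
Middle temporal gyrus,MTG,Left,-46,-61,21
Middle temporal gyrus,MTG,Left,-58,-26,-15
Middle temporal gyrus,MTG,Right,58,-53,-14
Middle temporal gyrus,MTG,Right,51,-29,-4
Precentral gyrus,PrCG,Left,-45,0,9
Precentral gyrus,PrCG,Left,-55,-9,12
Precentral gyrus,PrCG,Right,20,-29,60
Precentral gyrus,PrCG,Right,44,-8,57
Precentral gyrus,PrCG,Right,51,-6,32
Precentral gyrus,PrCG,Right,56,-5,13
Thalamus,Th,Left,-10,-18,7
Thalamus,Th,Right,9,-4,6
Insula,In,Left,-38,-33,17
Insula,In,Right,32,-26,13
Insula,In,Right,36,22,3
Superior temporal gyrus,STG,Left,-51,8,-2
Superior temporal gyrus,STG,Left,-49,-26,5
Superior temporal gyrus,STG,Left,-44,12,-34
Superior temporal gyrus,STG,Right,65,-33,20
Inferior temporal gyrus,ITG,Left,-56,-45,-24
Inferior temporal gyrus,ITG,Left,-50,-7,-39
Inferior temporal gyrus,ITG,Right,65,-12,-19
Inferior temporal gyrus,ITG,Right,49,-3,-38
Cuneus,Cu,Left,-8,-81,7
Cuneus,Cu,Left,-14,-91,31
Cuneus,Cu,Left,-3,-81,21
Middle occipital gyrus,MOG,Left,-26,90,3
Middle occipital gyrus,MOG,Right,37,-81,1
Inferior occipital gyrus,IOG,Left,,,
Inferior occipital gyrus,IOG,Right,27,-97,-13
Inferior occipital gyrus,IOG,Right,43,-78,-12
Lingual gyrus,LG,Left,-25,-98,-12
Lingual gyrus,LG,Left,-12,-95,-13
Lingual gyrus,LG,Left,-15,-72,-8
Lingual gyrus,LG,Right,26,-79,-16
Anterior cingulate,AC,Left,-3,42,16
Anterior cingulate,AC,Left,-11,26,25
Anterior cingulate,AC,Right,10,22,27
Anterior cingulate,AC,Right,12,36,20
Postcentral gyrus,PoCG,Left,-7,-33,72
Postcentral gyrus,PoCG,Left,-40,-19,54
Postcentral gyrus,PoCG,Left,-29,-43,61
Postcentral gyrus,PoCG,Left,-21,-31,61
Postcentral gyrus,PoCG,Right,13,-33,75
Postcentral gyrus,PoCG,Right,10,-46,73
Postcentral gyrus,PoCG,Right,29,-39,59
Postcentral gyrus,PoCG,Right,50,-20,42
Postcentral gyrus,PoCG,Right,42,-20,55
Medial frontal gyrus,MlFG,Left,-3,2,53
Medial frontal gyrus,MlFG,Left,-3,44,-9
Medial frontal gyrus,MlFG,Left,-11,45,8
Medial frontal gyrus,MlFG,Left,-2,38,36
Medial frontal gyrus,MlFG,Left,-3,26,44
Medial frontal gyrus,MlFG,Right,2,-28,60
Medial frontal gyrus,MlFG,Right,3,-17,58
Medial frontal gyrus,MlFG,Right,7,8,51
Medial frontal gyrus,MlFG,Right,6,64,22
Medial frontal gyrus,MlFG,Right,8,42,-5
Superior frontal gyrus,SFG,Left,-18,63,-9
Superior frontal gyrus,SFG,Left,-16,29,53
Superior frontal gyrus,SFG,Left,-10,55,39
Superior frontal gyrus,SFG,Left,-20,64,19
Superior frontal gyrus,SFG,Left,-21,41,-20
Superior frontal gyrus,SFG,Left,-39,51,17
Superior frontal gyrus,SFG,Right,10,-17,74
Superior frontal gyrus,SFG,Right,22,39,39
Superior frontal gyrus,SFG,Right,13,55,38
Superior frontal gyrus,SFG,Right,13,30,59
Superior frontal gyrus,SFG,Right,26,50,27
Precuneus,PrCu,Left,-7,-52,61
Precuneus,PrCu,Left,-7,-71,42
Precuneus,PrCu,Left,-16,-77,34
Precuneus,PrCu,Right,15,-63,26
Precuneus,PrCu,Right,4,-48,51
Precuneus,PrCu,Right,10,-62,61
Superior parietal lobule,SPL,Left,-17,-59,64
Superior parietal lobule,SPL,Right,25,-58,60
Cingulate gyrus,CG,Left,-14,-18,40
Cingulate gyrus,CG,Left,-2,-37,44
Cingulate gyrus,CG,Left,-2,-35,31
Cingulate gyrus,CG,Left,-1,15,44
Cingulate gyrus,CG,Right,8,-48,31
Cingulate gyrus,CG,Right,5,23,37
Claustrum,Cl,Left,-34,3,4
Claustrum,Cl,Right,,,
Posterior cingulate,PoC,Left,-11,-56,16
Posterior cingulate,PoC,Left,-3,-49,13
Posterior cingulate,PoC,Right,11,-54,17
Fusiform gyrus,FG,Left,-34,-38,-16
Fusiform gyrus,FG,Left,-31,-10,-36
Fusiform gyrus,FG,Right,46,-47,-17
Uncus,Un,Left,,,
Uncus,Un,Right,33,-12,-34
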
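name,chemical_class,annotations,descriptors,valence
acetaldehyde,Aldehyde,2,fruity,positive
2-methylfuran,Furan,1A;1R,roasted,neutral
3-methylbutanal,Aldehyde,1A;1R;3,fruity,positive
"2,3-butanedione",Ketone,1A;1R,sweet,positive
"2,3-pentanedione",Ketone,1A;1R;3,sweet,positive
hexanal,Aldehyde,1A;3,fruity,negative
1-methyl-1H-pyrrole,Pyrrole,1A;3,musty,negative
pyridine,Heterocyclic N,2,sour,negative
pyrazine,Pyrazine,1R;2,nutty;roasted,positive
2-methyl-pyrazine,Pyrazine,2;3,nutty;roasted,positive
acetoin,Ketone,1A,sweet,positive
acetol,Ketone,4,sweet,neutral
"2,5-dimethylpyrazine",Pyrazine,1A;1R;3,nutty;roasted,positive
"2,6-dimethylpyrazine",Pyrazine,1A;1R;3,nutty;roasted,positive
ethylpyrazine,Pyrazine,1A;1R,nutty;roasted,positive
"2,3-dimethylpyrazine",Pyrazine,3,nutty;roasted,positive
1-hydroxy-2-butanone,Ketone,1A;1R,sweet,neutral
3-ethylpyridine,Heterocyclic N,2,roasted,neutral
2-ethyl-6-methylpyrazine,Pyrazine,1A;1R;3,nutty;roasted,positive
2-ethyl-5-methylpyrazine,Pyrazine,1A;1R;3,nutty;roasted,positive
2-ethyl-3-methylpyrazine,Pyrazine,3,nutty;roasted,positive
"2,3-diethylpyrazine",Pyrazine,4,nutty,positive
"3-ethyl-2,5-dimethylpyrazine",Pyrazine,3,nutty;roasted,positive
acetic acid,Acid,1A,sour,negative
furfural,Aldehyde,1A;1R,sweet,positive
acetoxyacetone,Ketone,4,sweet,neutral
furfurylmethyl sulphide,Sulphide,4,roasted,negative
"2-ethyl-3,5-dimethylpyrazine",Pyrazine,4,nutty;roasted,positive
furaneol,Ketone,4,sweet,positive
2-acetylfuran,Furan,4,sweet;roasted,positive
ethyl propanoate,Ester,3,fruity,positive
2-furanmethanol acetate,Acetate,1A;1R;3,fruity;sweet,positive
propanoic acid,Acid,2,sour,negative
5-methylfurfural,Aldehyde,3,sweet;spicy,positive
"2,3-butanediol",Alcohol,4,sweet,neutral
2-formyl-1-methylpyrrole,Pyrrole,1R;4,roasted,neutral
γ-butyrolactone,Ketone,4,sweet,neutral
2-furanmethanol,Alcohol,1A,roasted,negative
3-methyl-butanoic acid,Acid,1A,sour,negative
N-acetyl-4(H)-pyridine,Heterocyclic N,1A;1R,roasted,neutral
"3-hydroxy-4,5-dimethyl-2(5H)-furanone",Ketone,4,spicy;sweet,positive
3-methoxy-5-methyl-2-cyclopenten-1-one,Ketone,4,sweet,neutral
3-methyl-2-butenoic acid,Acid,1A;1R,sour,negative
"3-methyl-1,2-cyclopentanedione",Ketone,3,sweet;roasted,positive
guaiacol,Phenolic,1R;3,spicy,positive
2-(1H-pyrrol-2-yl)-ethanone,Ketone,4,nutty;musty,neutral
2-formylpyrrole,Pyrrole,4,musty;roasted,negative
phenol,Phenolic,1A;1R,spicy;musty,negative
4-ethylguaiacol,Phenolic,1A;1R;3,spicy,positive
4-vinylguaiacol,Phenolic,1A;1R;3,spicy,positive
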
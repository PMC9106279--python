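# integer-valence fixture lexicon (schema: token<TAB>score in [-5,5] \ {0})
excelente	5
optimo	4
feliz	3
contento	2
mejor	2
mejoria	2
animado	2
alivio	2
agradable	2
tranquilo	1
estable	1
bien	1
comodo	1
incomodo	-1
confuso	-1
dolor	-2
fiebre	-2
agitado	-2
triste	-2
peor	-2
ansioso	-2
llanto	-2
grave	-3
vomito	-3
critico	-3
terrible	-4
fatal	-4
horrible	-5
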
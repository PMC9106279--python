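# binary polarity fixture lexicon (schema: token<TAB>positive|negative)
feliz	positive
contento	positive
tranquilo	positive
estable	positive
mejor	positive
mejoria	positive
bien	positive
comodo	positive
animado	positive
alivio	positive
activo	positive
colaborador	positive
favorable	positive
optimo	positive
agradable	positive
dolor	negative
fiebre	negative
agitado	negative
triste	negative
peor	negative
grave	negative
incomodo	negative
ansioso	negative
vomito	negative
llanto	negative
confuso	negative
febril	negative
inquieto	negative
desfavorable	negative
critico	negative
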
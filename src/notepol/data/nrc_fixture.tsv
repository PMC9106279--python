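# emotion-category fixture lexicon (schema: token<TAB>category; one line per (token, category) pair)
feliz	joy
feliz	positive
contento	joy
contento	positive
tranquilo	trust
tranquilo	positive
estable	trust
estable	positive
mejoria	anticipation
mejoria	joy
mejoria	positive
animado	joy
animado	anticipation
animado	positive
confianza	trust
confianza	positive
alivio	joy
alivio	positive
sonrisa	joy
sonrisa	positive
colaborador	trust
colaborador	positive
dolor	sadness
dolor	negative
fiebre	fear
fiebre	negative
agitado	anger
agitado	negative
triste	sadness
triste	negative
miedo	fear
miedo	negative
ansioso	fear
ansioso	anticipation
ansioso	negative
grave	fear
grave	negative
vomito	disgust
vomito	negative
llanto	sadness
llanto	negative
enfado	anger
enfado	negative
sorpresa	surprise
sobresalto	surprise
sobresalto	fear
sobresalto	negative
rechazo	disgust
rechazo	anger
rechazo	negative
empeora	sadness
empeora	fear
empeora	negative
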
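# lemma table fixture (schema: surface<TAB>lemma)
tranquila	tranquilo
agitada	agitado
dolores	dolor
contenta	contento
estables	estable
comoda	comodo
ansiosa	ansioso
confusa	confuso
corriendo	correr
mejorando	mejoria
inquieta	inquieto
activa	activo
animada	animado
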
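# valence-shifter fixture lexicon (schema: token<TAB>negator|amplifier|deamplifier)
no	negator
nunca	negator
sin	negator
tampoco	negator
nada	negator
ni	negator
muy	amplifier
mucho	amplifier
bastante	amplifier
extremadamente	amplifier
totalmente	amplifier
claramente	amplifier
poco	deamplifier
apenas	deamplifier
algo	deamplifier
ligeramente	deamplifier
levemente	deamplifier
escasamente	deamplifier
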
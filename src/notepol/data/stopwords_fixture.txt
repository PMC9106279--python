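el
la
los
las
un
una
de
del
en
y
o
a
que
se
con
por
para
su
es
esta
al
lo
le
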
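# Abbreviations that keep a trailing period attached (stored without the period).
Fig
Figs
Eq
Eqs
Anal
Calcd
calcd
obsd
cf
ca
eq
equiv
et
al
etc
vs
e.g
i.e
Dr
Prof
No
no
Ref
ref
approx
temp
sat
aq
conc
dec
lit
mp
bp
m.p
b.p
rt
min
hr
hrs
sec
mol
wt
vol
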
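# Last two levels of a MAPK cascade (the "2+2" motif): two distributive
# double-phosphorylation cycles in series, mass action, arbitrary units.
# Level 2: kinase K (K0/K1/K2) phosphorylated by the input kinase E1,
# dephosphorylated by phosphatase P2.  Level 3: substrate A (A/Ap/App)
# phosphorylated by free K2, dephosphorylated by P3.
# a = association, d = dissociation, k = catalytic, per reaction.
a1 = 100.0
d1 = 1.0
k1 = 0.32
a2 = 100.0
d2 = 1.0
k2 = 21.0
a3 = 100.0
d3 = 1.0
k3 = 20.0
a4 = 100.0
d4 = 1.0
k4 = 1.0
a5 = 100.0
d5 = 1.0
k5 = 0.12
a6 = 100.0
d6 = 1.0
k6 = 1.0
a7 = 100.0
d7 = 1.0
k7 = 3.0
a8 = 100.0
d8 = 1.0
k8 = 0.63
Ktot = 1.0
Atot = 8.0
P2tot = 0.165
P3tot = 0.13
E1tot = 0.26
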
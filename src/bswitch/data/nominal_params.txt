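# kinetic parameters (units 1/s; Michaelis constants dimensionless)
a0 = 0.3
a1 = 3.0
a2 = 5.0
a3 = 0.1
a4 = 15.0
a5 = 0.02
a6 = 0.1
a7 = 0.05
a8 = 0.05
a9 = 4.0
a10 = 0.05
a11 = 0.5
a12 = 0.02
b0 = 0.02
b1 = 2.0
b2 = 6.0
b3 = 1.0
b4 = 18.0
c0 = 0.005
c1 = 0.8
c2 = 0.2
c3 = 4.0
d0 = 0.02
d1 = 1.0
e0 = 0.05
e1 = 3.0
e2 = 2.0
e3 = 10.0
e4 = 8.0
e5 = 15.0
e6 = 10.0
f0 = 0.05
f1 = 2.0
f2 = 1.0
f3 = 4.0
g0 = 0.05
g1 = 2.0
g2 = 5.0
h0 = 0.02
h1 = 1.0
i0 = 0.2
j0 = 0.1
j1 = 0.5
mu1 = 1.0
mu2 = 1.0
mu3 = 1.0
mu4 = 1.0
mu5 = 1.0
mu6 = 1.0
mu7 = 1.0
mu8 = 1.0
mu9 = 1.0
mu10 = 1.0
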
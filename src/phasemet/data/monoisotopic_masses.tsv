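element	mass_da
H	1.00782503207
C	12.0
N	14.0030740048
O	15.9949146196
F	18.9984031627
Na	22.9897692820
Si	27.9769265347
P	30.9737619984
S	31.9720711744
Cl	34.9688526820
K	38.9637064864
Br	78.9183376000
I	126.9044719000
Sn	119.9022016300
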
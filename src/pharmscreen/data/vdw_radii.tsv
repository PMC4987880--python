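# Bondi van der Waals radii (angstrom); fallback 1.7 for unlisted elements.
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
Cl	1.75
Br	1.85
I	1.98
B	1.92
Si	2.10
Se	1.90
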
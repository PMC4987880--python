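# Pharmacophore feature definitions: kind <TAB> SMARTS <TAB> center
# center = "first" (feature per first matched atom) or "all" (one feature per
# match, centered on the centroid of all matched atoms).
# Aromatic rings and hydrophobic clusters are detected algorithmically (ring
# perception / carbon-cluster growth) and have no rows here.
HydrogenDonor	[$([N;!H0;+0]),$([N;!H0;+1])]	first
HydrogenDonor	[$([O;H1;+0])]	first
HydrogenDonor	[$([S;H1;+0])]	first
HydrogenDonor	[$([n;H1])]	first
HydrogenAcceptor	[$([O;H1;v2;+0])]	first
HydrogenAcceptor	[$([O;H0;v2;+0])]	first
HydrogenAcceptor	[$([O;-;!$([O-]~[+])])]	first
HydrogenAcceptor	[$([S;H0;v2;+0;!$(S=*)])]	first
HydrogenAcceptor	[$([N;v3;+0;!$(N-*=[O,N,S]);!$(N-a);!$(N#*);!$(N=*)])]	first
HydrogenAcceptor	[$([n;H0;+0;X2])]	first
HydrogenAcceptor	[$([NX2;H0;v3;+0;!$(N~[O,S]);!$(N=N)])]	first
PositiveIon	[$([+,+2,+3;!$(*~[-])])]	first
PositiveIon	N-C(=[NX2])-N	all
PositiveIon	C(=[NX2;!$(N-a)])-[NX3]	all
PositiveIon	c1cnc[nH]1	all
PositiveIon	[$([N;H2,H3;v3,v4;!$(N-a);!$(N-*=[O,N,S]);!$(N~[!#6;!#1])])]	first
NegativeIon	C(=O)[O;H1,X1-]	all
NegativeIon	[SX4](=O)(=O)[O;H1,X1-]	all
NegativeIon	[PX4](=O)[O;H1,X1-]	all
NegativeIon	c1nnn[n;H1,X2-]1	all
NegativeIon	[$([-,-2;!$(*~[+])])]	first
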
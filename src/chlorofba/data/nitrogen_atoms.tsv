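species	n_atoms
ALA	1
AdoHcy	1
Chla	4
Chlide	4
CoproIII	4
DVPchlide	4
Gln	2
Glu	1
Gly	1
HMB	4
Hcy	1
Met	1
MgPP	4
MgPPME	4
NH3	1
PBG	2
PSer	1
Pchlide	4
ProtoIX	4
ProtogenIX	4
SAM	1
Ser	1
UroIII	4
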
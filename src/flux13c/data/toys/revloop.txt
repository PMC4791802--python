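# Reversible interconversion with label exchange plus a rearranging
# reversible step (tests exchange-flux handling).
# reactions: 4
# METABOLITES
A      input  extracellular  3  no
B      mid    cytosol        3  yes
C      mid2   cytosol        3  yes
C_ext  out    extracellular  3  no
# REACTIONS
R1 : 1 A -> 1 B | irr | map A#abc -> B#abc
R2 : 1 B -> 1 C | rev | map B#abc -> C#cab
R3 : 1 C -> 1 C_ext | irr | map C#abc -> C_ext#abc
R4 : 1 B -> 1 C | rev | map B#abc -> C#abc
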
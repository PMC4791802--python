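# Linear chain A -> B -> C -> export, two carbons each.
# reactions: 3
# METABOLITES
A      pool-A      extracellular  2  no
B      pool-B      cytosol        2  yes
C      pool-C      cytosol        2  yes
C_ext  pool-C-out  extracellular  2  no
# REACTIONS
R1 : 1 A -> 1 B | irr | map A#ab -> B#ab
R2 : 1 B -> 1 C | irr | map B#ab -> C#ab
R3 : 1 C -> 1 C_ext | irr | map C#ab -> C_ext#ab
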
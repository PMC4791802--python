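# Symmetric 4-carbon intermediate: half-weight atom-map variants scramble
# the orientation before an asymmetric cleavage.
# reactions: 4
# METABOLITES
A      input      extracellular  4  no
S      symmetric  cytosol        4  yes
M      product    cytosol        4  yes
T      two-carbon cytosol        2  yes
T_ext  out        extracellular  2  no
M2_ext out2       extracellular  2  no
# REACTIONS
R1 : 1 A -> 1 S | irr | map A#abcd -> S#abcd @0.5 ; A#abcd -> S#dcba @0.5
R2 : 1 S -> 1 M | irr | map S#abcd -> M#abcd
R3 : 1 M -> 1 T + 1 M2_ext | irr | map M#abcd -> T#ab + M2_ext#cd
R4 : 1 T -> 1 T_ext | irr | map T#ab -> T_ext#ab
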
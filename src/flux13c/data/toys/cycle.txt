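# Miniature condensation/decarboxylation cycle (TCA-like): a 2-carbon unit
# condenses with a regenerated 3-carbon acceptor; two decarboxylations
# close the loop; anaplerotic input replenishes the acceptor.
# reactions: 5
# METABOLITES
AC     acetyl-unit   extracellular  2  no
AN     anaplerotic   extracellular  3  no
co2    co2-sink      cytosol        1  no
OX     acceptor      cytosol        3  yes
CT     condensate    cytosol        5  yes
KG     keto-acid     cytosol        4  yes
KG_ext drain         extracellular  4  no
# REACTIONS
RCS : 1 AC + 1 OX -> 1 CT | irr | map AC#ab + OX#cde -> CT#abcde
RDC : 1 CT -> 1 KG + 1 co2 | irr | map CT#abcde -> KG#abcd + co2#e
RKD : 1 KG -> 1 OX + 1 co2 | irr | map KG#abcd -> co2#a + OX#bcd
RAN : 1 AN -> 1 OX | irr | map AN#abc -> OX#abc
RKX : 1 KG -> 1 KG_ext | irr | map KG#abcd -> KG_ext#abcd
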
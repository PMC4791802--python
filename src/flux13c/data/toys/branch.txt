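# Split of a 3-carbon input into 2C + 1C units that recondense (convolution
# path) in competition with direct conversion (convergent branch point).
# reactions: 4
# METABOLITES
X      input        extracellular  3  no
P      split-2c     cytosol        2  yes
Q      split-1c     cytosol        1  yes
W      condensed    cytosol        3  yes
W_ext  product-out  extracellular  3  no
# REACTIONS
RIN  : 1 X -> 1 W | irr | map X#abc -> W#abc
RSPL : 1 X -> 1 P + 1 Q | irr | map X#abc -> P#ab + Q#c
RCND : 1 P + 1 Q -> 1 W | irr | map P#ab + Q#c -> W#cab
REXP : 1 W -> 1 W_ext | irr | map W#abc -> W_ext#abc
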
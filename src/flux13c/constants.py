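"""Isotope abundance constants used throughout the package.

Natural isotope abundances (mole fractions) for the elements that occur in
TBDMS-derivatized amino-acid fragment ions.  Values are the IUPAC
representative terrestrial abundances; for each element the entry is the
probability distribution over the nominal mass shift (+0, +1, +2 Da)
contributed by a single atom of that element.
"""

#: natural abundance of 13C (per carbon atom)
NATURAL_13C = 0.0107

#: per-atom mass-shift distributions, index = mass shift in Da
ISOTOPE_SHIFT = {
    "C": (1.0 - NATURAL_13C, NATURAL_13C),
    "H": (1.0 - 0.000115, 0.000115),
    "N": (1.0 - 0.00364, 0.00364),
    "O": (1.0 - 0.00038 - 0.00205, 0.00038, 0.00205),
    "Si": (1.0 - 0.046832 - 0.030872, 0.046832, 0.030872),
}
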
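"""Unit conversion constants (internal arithmetic is Hartree/Bohr)."""

HARTREE_TO_EV = 27.211386
ANGSTROM_TO_BOHR = 1.8897259886
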
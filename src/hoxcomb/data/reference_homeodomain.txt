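# Synthetic neutral reference homeodomain (60 aa), used by the generator
# for all positions that are not class-diagnostic, and as the base row of
# the bundled seed alignment. It is an Antennapedia-style homeodomain in
# which every shipped diagnostic position (central: 6, 26-31, 59;
# posterior: 3, 14, 18, 20, 21) holds a residue that matches NO shipped
# diagnostic constraint, so that class membership of generated records is
# decided entirely by the residues the generator forces. Edit with care:
# the neutrality property above is what classification tests rely on.
RKRGRSTYTRYQTLELEKEFHFNRYMSGSGSIEIAHALCLTERQIKIWFQNRRMKWKKDN
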
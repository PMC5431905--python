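"""Exception hierarchy.

``HoxcombError`` is the base class for everything the library raises on
purpose; ``DataError`` marks problems with user-supplied input (malformed
FASTA, ragged alignments, bad signature tables) so the command-line layer
can map them to a distinct exit code.
"""


class HoxcombError(Exception):
    """Base class for all errors raised deliberately by hoxcomb."""


class DataError(HoxcombError):
    """Malformed or inconsistent input data."""
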
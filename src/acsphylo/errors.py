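"""Exception hierarchy for acsphylo."""


class AcsPhyloError(Exception):
    """Base class for all acsphylo errors."""


class InvalidInputError(AcsPhyloError):
    """Malformed or out-of-contract input (empty sequences, bad matrices, ...)."""


class InvalidAlphabetError(InvalidInputError):
    """Residue symbols collide with the index's reserved sentinel range."""


class FormatError(AcsPhyloError):
    """A file does not conform to its declared format (FASTA, PHYLIP, Newick)."""


class NewickParseError(FormatError):
    """Malformed Newick string; carries the character offset of the failure."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position
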
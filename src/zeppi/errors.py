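"""Exception hierarchy.

Every stage of the scoring pipeline raises a distinct subclass so that
callers (notably decoy evaluation, which must record unscoreable models
instead of aborting) can catch :class:`ZeppiError` and keep going.
"""


class ZeppiError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(ZeppiError):
    """File could not be parsed as PDB or mmCIF."""


class ChainNotFoundError(ZeppiError):
    """Requested chain label is absent from the structure."""


class EmptyChainError(ZeppiError):
    """Chain exists but contains no protein residues with heavy atoms."""


class EmptyInterfaceError(ZeppiError):
    """No inter-chain heavy-atom contact under the cutoff: model unscoreable."""


class SequenceStructureMismatchError(ZeppiError):
    """Structure sequence aligns to the MSA query below the identity floor."""


class MsaFormatError(ZeppiError):
    """Alignment file unreadable or rows of inconsistent length."""


class NoSpeciesLabelsError(ZeppiError):
    """No row of the MSA carries a parseable species label."""


class NoPairedRowsError(ZeppiError):
    """The two MSAs share no species (after filtering)."""


class UnscoreableModelError(ZeppiError):
    """No contact survives MSA mapping and column filtering."""


class InterfaceTooLargeError(ZeppiError):
    """A chain has fewer non-interface residues than interface residues,
    so an injective fake interface cannot be drawn."""


class DegenerateInputError(ZeppiError):
    """Input too small or constant for the requested computation."""
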
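"""Exception hierarchy for urnmap."""


class UrnmapError(Exception):
    """Base class for all urnmap errors."""


class FormatError(UrnmapError):
    """The input file could not be parsed as PDB or mmCIF."""


class RoleAssignmentError(UrnmapError):
    """No viable alpha/beta/peptide chain-role assignment was found."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates or [])


class AmbiguityError(RoleAssignmentError):
    """Two or more chains tie for the same role; an explicit config is needed."""


class EmptyContactMapError(UrnmapError):
    """The peptide has no modeled residue that can carry contacts."""


class HomologyError(UrnmapError):
    """Chain identity against the prototype fell below the configured floor."""


class NoAnchorError(UrnmapError):
    """No peptide residue reaches the required overlap with the prototype
    anchor's partner set; the complex cannot be put into the unified numbering.

    ``ranked`` holds (residue_index, overlap, n_contacts) for every candidate
    register so alternatives can still be inspected.
    """

    def __init__(self, message, ranked=None):
        super().__init__(message)
        self.ranked = list(ranked or [])


class GroupMismatchError(UrnmapError):
    """Structures from different groups (DR vs DQ) were mixed in aggregation."""


class GeometryError(UrnmapError):
    """A fixture specification is not geometrically realizable."""


class TableError(UrnmapError):
    """A property/CPS table is incomplete or malformed."""
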
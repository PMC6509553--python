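"""Exception types shared across the package."""


class PhylostructError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PhylostructError, ValueError):
    """Raised for malformed Newick/NEXUS input."""


class MissingBranchLengthError(PhylostructError, ValueError):
    """An operation needed branch lengths but some edges are undated.

    Branch lengths are never silently treated as zero; run ``bladj`` (or
    supply a fully dated tree) first.
    """


class UngraftableSpeciesError(PhylostructError, ValueError):
    """Some species could not be attached to the backbone.

    Attributes
    ----------
    species : list of str
        The species whose family was absent from the backbone.
    """

    def __init__(self, species):
        self.species = list(species)
        super().__init__(
            "ungraftable species (family absent from backbone): "
            + ", ".join(self.species)
        )


class AgeConflictError(PhylostructError, ValueError):
    """Node ages violate age(parent) >= age(child)."""


class PipelineError(PhylostructError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
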
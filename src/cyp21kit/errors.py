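"""Exception hierarchy for cyp21kit."""


class Cyp21kitError(Exception):
    """Base class for all cyp21kit errors."""


class ConfigurationError(Cyp21kitError):
    """A locus-model or simulation configuration violates a documented invariant."""


class UnknownVariantError(Cyp21kitError, LookupError):
    """A variant token has no registered landmark site.

    Callers that merely need a location may treat this as "location unknown"
    rather than fatal.
    """


class NonCanonicalHaplotypeError(Cyp21kitError):
    """A marker vector interleaves gene- and pseudogene-origin calls 5'->3'.

    Such a haplotype cannot be produced by a single pseudogene->gene junction
    and falls outside the single-junction chimera model.
    """

    def __init__(self, gene_site: str, pseudo_site: str):
        self.gene_site = gene_site
        self.pseudo_site = pseudo_site
        super().__init__(
            f"gene-origin call at {gene_site} precedes pseudogene-origin call "
            f"at {pseudo_site}: haplotype is outside the single-junction model"
        )


class InconsistentEvidenceError(Cyp21kitError):
    """Variant-level and structural evidence for one allele contradict."""


class CohortParseError(Cyp21kitError):
    """A cohort file does not parse under the documented schema."""


class UndefinedStatisticError(Cyp21kitError):
    """A statistic is undefined for the given input (empty margin, zero variance)."""
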
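"""Exception hierarchy for the diagnostic-SNP pipeline."""


class CitrusDiagError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CitrusDiagError):
    """Invalid simulation or panel configuration (e.g. undeclared hybrid parent)."""


class VcfParseError(CitrusDiagError):
    """Malformed VCF input; message names the offending record."""


class FixtureCorruptionError(CitrusDiagError):
    """Packaged reference-table fixture failed its checksum."""


class PhaseConflictError(CitrusDiagError):
    """A diploid genotype is incompatible with the haplotype being complemented.

    Signals a genotyping error or a wrong haploid-derivative link; carries the
    offending site in ``site``.
    """

    def __init__(self, message: str, site=None):
        super().__init__(message)
        self.site = site


class AmbiguousParentageError(CitrusDiagError):
    """Neither, or both, candidate parents are compatible with a haplotype."""


class PedigreeConflictError(CitrusDiagError):
    """An accession's genotype lacks the allele its documented fixed parent carries."""


class InternalConsistencyError(CitrusDiagError):
    """An invariant that should hold by construction was violated."""
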
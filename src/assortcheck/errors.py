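"""Exception hierarchy shared across the package."""


class AssortcheckError(Exception):
    """Base class for all package-specific failures."""


class ValidationError(AssortcheckError):
    """Input data violates a structural invariant (ids, dimensions, codes)."""


class FeasibilityError(AssortcheckError):
    """An (f, p) combination lies outside the feasible genotype simplex."""


class MonomorphicError(AssortcheckError):
    """A locus has allele frequency 0 or 1 where polymorphism is required."""


class PlinkFormatError(AssortcheckError):
    """Malformed PLINK BED/BIM/FAM input (magic bytes, payload size, ids)."""
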
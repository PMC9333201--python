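"""Exception hierarchy."""


class PgxError(Exception):
    """Base class for all package errors."""


class CatalogError(PgxError):
    """Invalid or inconsistent catalog / translation-table input."""


class VariantIOError(PgxError):
    """Problems reading, merging, or filtering variant tables."""


class DepthError(PgxError):
    """Problems with depth-of-coverage input or normalization."""


class ClassifierError(PgxError):
    """Structural-variant classifier misuse (training or prediction)."""


class GenotypeError(PgxError):
    """Haplotype matching / diplotype assignment failures."""


class PhenotypeError(PgxError):
    """Phenotype prediction misuse (unsupported gene, bad tables)."""


class ComparisonError(PgxError):
    """Call-set comparison failures (empty intersections, bad ledgers)."""
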
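"""Exception hierarchy for meltcall."""


class MeltcallError(Exception):
    """Base class for all meltcall errors."""


class InvalidCurveError(MeltcallError):
    """A dissociation or melting curve violates its invariants."""


class InvalidAssayError(MeltcallError):
    """A SNP assay definition violates its invariants (e.g. Tm(A) >= Tm(B))."""


class InvalidParamsError(MeltcallError):
    """Synthetic-curve parameters violate their invariants."""


class TrainingDataError(MeltcallError):
    """Labelled training wells are insufficient (e.g. a genotype class is absent)."""


class DataIntegrityError(MeltcallError):
    """An input file is structurally broken (duplicates, non-numeric cells...)."""
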
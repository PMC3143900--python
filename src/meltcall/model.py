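"""Proportional-odds genotype calling from the adjusted signal ratio.

The three diploid genotypes AA (class 1), AB (class 2) and BB (class 3)
are ordered: the heterozygote's signal ratio lies between the two
homozygotes'.  A cumulative-logit (proportional-odds) model with a single
covariate, the adjusted signal-strength ratio X = x - delta, captures
this ordering:

    logit P(Z <= 1) = alpha1 - beta * X
    logit P(Z <= 2) = alpha2 - beta * X

from which the individual class probabilities follow by differencing.
A call is made only when the winning class's probability exceeds BOTH
others by more than a margin rho; otherwise the well is flagged "no call"
for human review.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .curves import MeltingCurve
from .peaks import SnpAssayDef, peak_readout

__all__ = [
    "OrdinalCallModel",
    "AlleleProbabilities",
    "CallResult",
    "CallReason",
    "Call",
    "PRESETS",
    "get_preset",
    "adjust_ratio",
    "allele_probabilities",
    "call_base",
    "call_well",
]


class Call(str, enum.Enum):
    """Genotype call categories; values are the ordinal class labels."""

    ALLELE1 = "allele1"  # homozygous AA
    ALLELE2 = "allele2"  # heterozygous AB
    ALLELE3 = "allele3"  # homozygous BB
    NO_CALL = "no_call"

    @property
    def ordinal(self) -> int | None:
        """Ordered class number 1/2/3, or None for a no-call."""
        return {"allele1": 1, "allele2": 2, "allele3": 3}.get(self.value)


class CallReason(str, enum.Enum):
    OK = "ok"
    MARGIN_TOO_SMALL = "margin_too_small"
    NO_PEAKS = "no_peaks"


@dataclass(frozen=True)
class OrdinalCallModel:
    """Coefficients of the shared calling model.

    alpha1 < alpha2 is required so the cumulative probabilities are
    ordered for every X; beta > 0 orients the model so that higher X
    (stronger B signal) favours class 3.
    """

    alpha1: float
    alpha2: float
    beta: float
    rho: float = 0.05

    def __post_init__(self) -> None:
        if not self.alpha1 < self.alpha2:
            raise ValueError(
                f"alpha1 must be < alpha2 (got {self.alpha1} >= {self.alpha2})"
            )
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not 0 <= self.rho < 0.5:
            raise ValueError(f"rho must be in [0, 0.5), got {self.rho}")


#: Named coefficient presets. "paper-2011" is the published demonstration
#: fit (12 SNPs x 44 individuals) with its demonstration margin rho = 0.05.
PRESETS: dict[str, OrdinalCallModel] = {
    "paper-2011": OrdinalCallModel(alpha1=15.3, alpha2=35.8, beta=51.0, rho=0.05),
}


def get_preset(name: str) -> OrdinalCallModel:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class AlleleProbabilities:
    """Class probabilities (p1, p2, p3) summing to 1."""

    p1: float
    p2: float
    p3: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


@dataclass(frozen=True)
class CallResult:
    """Outcome of calling one well.

    ``probabilities``, ``x`` and ``x_adjusted`` are None only for
    peak-level no-calls (no signal in either region).
    """

    call: Call
    reason: CallReason
    probabilities: AlleleProbabilities | None = None
    x: float | None = None
    x_adjusted: float | None = None
    well_id: str = ""
    snp_id: str = ""


def adjust_ratio(x: float, delta: float) -> float:
    """Apply the SNP-specific offset: X = x - delta.

    The result may leave [0, 1]; it is deliberately not clamped, since the
    logistic link accepts any real X.
    """
    return x - delta


def allele_probabilities(model: OrdinalCallModel, x_adjusted: float) -> AlleleProbabilities:
    """Evaluate the three class probabilities at an adjusted ratio X.

    p1 = logistic(alpha1 - beta*X); p1 + p2 = logistic(alpha2 - beta*X);
    p3 is the complement.  The numerically stable logistic keeps this
    total for any real X.
    """
    p1 = float(expit(model.alpha1 - model.beta * x_adjusted))
    c12 = float(expit(model.alpha2 - model.beta * x_adjusted))
    p2 = max(c12 - p1, 0.0)  # guard vanishing fp negatives when both saturate
    return AlleleProbabilities(p1=p1, p2=p2, p3=1.0 - c12)


def call_base(probs: AlleleProbabilities, rho: float) -> Call:
    """Apply the margin rule to class probabilities.

    The branches are evaluated in a fixed order (allele 2, then 3, then 1);
    an allele is called iff its probability exceeds both others by strictly
    more than rho, otherwise the well is a no-call.  A gap exactly equal to
    rho, or exactly tied probabilities, falls through to no-call.
    """
    p1, p2, p3 = probs.p1, probs.p2, probs.p3
    if p2 - p1 > rho and p2 - p3 > rho:
        return Call.ALLELE2
    if p3 - p1 > rho and p3 - p2 > rho:
        return Call.ALLELE3
    if p1 - p2 > rho and p1 - p3 > rho:
        return Call.ALLELE1
    return Call.NO_CALL


def call_well(
    m: MeltingCurve, assay: SnpAssayDef, model: OrdinalCallModel
) -> CallResult:
    """Full per-well pipeline: peak readout -> offset -> probabilities -> call."""
    readout = peak_readout(m, assay)
    if not readout.detectable:
        return CallResult(
            call=Call.NO_CALL,
            reason=CallReason.NO_PEAKS,
            well_id=m.well_id,
            snp_id=m.snp_id or assay.snp_id,
        )
    x_adj = adjust_ratio(readout.x, assay.delta)
    probs = allele_probabilities(model, x_adj)
    call = call_base(probs, model.rho)
    reason = CallReason.OK if call is not Call.NO_CALL else CallReason.MARGIN_TOO_SMALL
    return CallResult(
        call=call,
        reason=reason,
        probabilities=probs,
        x=readout.x,
        x_adjusted=x_adj,
        well_id=m.well_id,
        snp_id=m.snp_id or assay.snp_id,
    )
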
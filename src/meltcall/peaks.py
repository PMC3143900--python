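"""Region-anchored peak detection and the signal-strength ratio.

In a Tm-shifted assay the two allele-specific PCR products are designed to
melt at distinct theoretical temperatures Tm(A) < Tm(B).  Each allele's
signal is therefore searched for in a temperature region anchored at its
theoretical Tm:

    R_A = (2*Tm(A) - Tm(B), (Tm(A) + Tm(B)) / 2]
    R_B = ((Tm(A) + Tm(B)) / 2, 2*Tm(B) - Tm(A)]

i.e. each region extends from its Tm by half the Tm gap on each side, so a
moderate drift of the real melting temperature from the theoretical one
stays inside the region.  Signal strengths D_A and D_B are the heights of
the tallest peaks in R_A and R_B after deducting the mean of the whole
melting curve; the signal-strength ratio x = D_B / (D_A + D_B) is the
B allele's share of the total signal and is the single covariate of the
downstream genotype-calling model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .curves import MeltingCurve
from .errors import InvalidAssayError

__all__ = [
    "SnpAssayDef",
    "SearchRegions",
    "PeakReadout",
    "search_regions",
    "detect_peak",
    "peak_readout",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpAssayDef:
    """Per-SNP assay definition.

    Attributes
    ----------
    snp_id : str
    tm_a, tm_b : float
        Theoretical melting temperatures (deg C) of the A- and B-allele
        PCR products; the assay design guarantees tm_a < tm_b.
    allele_a, allele_b : str
        Base labels (e.g. "C", "G") used to render genotype strings.
    delta : float
        SNP-specific offset in ratio units applied as X = x - delta;
        trained values are low-resolution (one decimal digit).
    """

    snp_id: str
    tm_a: float
    tm_b: float
    allele_a: str = "A"
    allele_b: str = "B"
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.tm_a < self.tm_b:
            raise InvalidAssayError(
                f"{self.snp_id}: requires Tm(A) < Tm(B), "
                f"got {self.tm_a} >= {self.tm_b}"
            )
        if not -0.5 <= self.delta <= 0.5:
            raise InvalidAssayError(
                f"{self.snp_id}: offset delta {self.delta} outside [-0.5, 0.5]"
            )


@dataclass(frozen=True)
class SearchRegions:
    """Half-open-left temperature intervals (lo, hi] for the two alleles."""

    lo_a: float
    hi_a: float
    lo_b: float
    hi_b: float


@dataclass(frozen=True)
class PeakReadout:
    """Baseline-deducted peak heights and the signal-strength ratio for one well.

    ``detectable`` is False exactly when both D_A and D_B are zero, in which
    case ``x`` is undefined (NaN) and the well is a no-call.
    """

    d_a: float
    d_b: float
    x: float
    detectable: bool


def search_regions(assay: SnpAssayDef) -> SearchRegions:
    """Compute the allele-specific peak-search regions for an assay.

    Both intervals are half-open on the left, closed on the right, and meet
    at the Tm midpoint (tm_a + tm_b) / 2.
    """
    mid = (assay.tm_a + assay.tm_b) / 2.0
    return SearchRegions(
        lo_a=2.0 * assay.tm_a - assay.tm_b,
        hi_a=mid,
        lo_b=mid,
        hi_b=2.0 * assay.tm_b - assay.tm_a,
    )


def detect_peak(m: MeltingCurve, region: tuple[float, float]) -> float | None:
    """Find the tallest peak of M inside a temperature region (lo, hi].

    The derivative of M restricted to the region is examined for sign
    changes: a +/- zero crossing is a peak (convex), a -/+ crossing a
    valley (concave).  Valleys are logged for diagnostics but never
    reported as the allele signal.  Peak height is the M value at the
    crossing sample (no sub-grid interpolation); on a plateau of exact
    zeros the last plateau index is taken, and ties between equally tall
    peaks go to the lower temperature.

    Returns
    -------
    float or None
        Height (raw M value) of the tallest peak, or ``None`` if the
        region contains no peak or is disjoint from the grid.
    """
    lo, hi = region
    mask = (m.temperatures > lo) & (m.temperatures <= hi)
    vals = m.values[mask]
    if vals.size < 3:
        if vals.size == 0:
            logger.debug(
                "well %s: region (%s, %s] disjoint from grid", m.well_id, lo, hi
            )
        return None

    d = np.diff(vals)
    best: float | None = None
    last_sign = 0
    for i in range(d.size):
        s = 0 if d[i] == 0 else (1 if d[i] > 0 else -1)
        if s == 0:
            continue
        if last_sign > 0 and s < 0:
            h = float(vals[i])  # last index of any zero plateau
            if best is None or h > best:
                best = h
        elif last_sign < 0 and s > 0:
            logger.debug(
                "well %s: valley at %.2f C (height %.4g) in (%s, %s]",
                m.well_id,
                m.temperatures[mask][i],
                vals[i],
                lo,
                hi,
            )
        last_sign = s
    return best


def peak_readout(m: MeltingCurve, assay: SnpAssayDef) -> PeakReadout:
    """Measure D_A, D_B and the ratio x for one well.

    The raw tallest-peak height in each region is normalised by deducting
    the mean of M over the full recorded grid; a missing peak, or one whose
    deducted height is negative, contributes zero.  When both signals are
    zero the well is flagged not detectable (a no-call upstream of the
    model); otherwise x = D_B / (D_A + D_B).
    """
    regions = search_regions(assay)
    mean = m.mean_height()

    def strength(lo: float, hi: float, label: str) -> float:
        h = detect_peak(m, (lo, hi))
        if h is None:
            return 0.0
        d = h - mean
        if d < 0:
            logger.debug(
                "well %s: %s peak below curve mean (%.4g < %.4g), clamped to 0",
                m.well_id,
                label,
                h,
                mean,
            )
            return 0.0
        return d

    d_a = strength(regions.lo_a, regions.hi_a, "A")
    d_b = strength(regions.lo_b, regions.hi_b, "B")
    if d_a == 0.0 and d_b == 0.0:
        return PeakReadout(d_a=0.0, d_b=0.0, x=float("nan"), detectable=False)
    return PeakReadout(d_a=d_a, d_b=d_b, x=d_b / (d_a + d_b), detectable=True)
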
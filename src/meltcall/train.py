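"""Training of SNP-specific offsets and the shared ordinal model.

Wells with genotypes known from Sanger sequencing provide labelled
signal-strength ratios x.  Training proceeds in two steps:

1. offsets: per-allele grand means <x> are taken across SNPs, each SNP's
   mean deviation from them becomes its offset delta (rounded to one
   decimal so most SNPs keep delta = 0);
2. coefficients: the cumulative-logit model is fit by maximum likelihood
   on the adjusted ratios X = x - delta.

These functions are thin wrappers over the scikit-learn style estimators
in :mod:`meltcall.estimators`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TrainingDataError
from .estimators import OrdinalGenotypeCaller, SnpOffsetCalibrator
from .model import OrdinalCallModel

__all__ = [
    "LabeledWell",
    "OrdinalFitResult",
    "grand_means",
    "fit_offsets",
    "fit_ordinal",
    "training_report",
]


@dataclass(frozen=True)
class LabeledWell:
    """One training observation: a signal ratio with its known genotype."""

    snp_id: str
    x: float
    genotype: int  # ordered class: 1 = AA, 2 = AB, 3 = BB

    def __post_init__(self) -> None:
        if self.genotype not in (1, 2, 3):
            raise TrainingDataError(
                f"genotype must be 1, 2 or 3, got {self.genotype!r}"
            )
        if not 0.0 <= self.x <= 1.0:
            raise TrainingDataError(f"x must be in [0, 1], got {self.x}")


@dataclass(frozen=True)
class OrdinalFitResult:
    """Fitted coefficients plus convergence diagnostics."""

    alpha1: float
    alpha2: float
    beta: float
    n_iter: int
    converged: bool
    separated: bool
    final_grad_norm: float
    loglik: float

    def model(self, rho: float = 0.05) -> OrdinalCallModel:
        return OrdinalCallModel(
            alpha1=self.alpha1, alpha2=self.alpha2, beta=self.beta, rho=rho
        )


def _calibrator(wells: Iterable[LabeledWell]) -> SnpOffsetCalibrator:
    ws = list(wells)
    if not ws:
        raise TrainingDataError("no labelled wells provided")
    frame = pd.DataFrame(
        {"snp_id": [w.snp_id for w in ws], "x": [w.x for w in ws]}
    )
    y = np.array([w.genotype for w in ws])
    return SnpOffsetCalibrator().fit(frame, y)


def grand_means(wells: Iterable[LabeledWell]) -> dict[int, float]:
    """Per-allele grand means <x>: unweighted averages of per-SNP class means."""
    return _calibrator(wells).grand_means_


def fit_offsets(wells: Iterable[LabeledWell]) -> dict[str, float]:
    """SNP-specific offsets delta, rounded half-away-from-zero to one decimal."""
    return _calibrator(wells).offsets_


def fit_ordinal(
    wells: Sequence[LabeledWell], offsets: Mapping[str, float]
) -> OrdinalFitResult:
    """Fit (alpha1, alpha2, beta) on adjusted ratios X = x - delta.

    All three genotype classes must be present.  (Near-)separated data make
    the likelihood unbounded; the fit is then capped and flagged via
    ``separated`` rather than raising.
    """
    ws = list(wells)
    x = np.array([w.x - offsets.get(w.snp_id, 0.0) for w in ws])
    y = np.array([w.genotype for w in ws])
    est = OrdinalGenotypeCaller().fit(x, y)
    return OrdinalFitResult(
        alpha1=est.alpha1_,
        alpha2=est.alpha2_,
        beta=est.beta_,
        n_iter=est.n_iter_,
        converged=est.converged_,
        separated=est.separated_,
        final_grad_norm=est.final_grad_norm_,
        loglik=est.loglik_,
    )


def training_report(
    calibrator: SnpOffsetCalibrator, fit: OrdinalFitResult
) -> str:
    """Human-readable tabular summary of a training run.

    Per-SNP class means, the unrounded deviation, the rounded delta, then
    the fitted coefficients and convergence diagnostics.
    """
    buf = io.StringIO()
    rows = []
    for snp, means in calibrator.class_means_.items():
        rows.append(
            {
                "snp_id": snp,
                "mean_x_allele1": means.get(1, float("nan")),
                "mean_x_allele2": means.get(2, float("nan")),
                "mean_x_allele3": means.get(3, float("nan")),
                "deviation": calibrator.deviations_[snp],
                "delta": calibrator.offsets_[snp],
            }
        )
    table = pd.DataFrame(rows)
    buf.write("# Per-SNP signal-ratio means and offsets\n")
    buf.write(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    gm = calibrator.grand_means_
    buf.write(
        f"\n\n# Grand means <x>: allele1={gm[1]:.4f} "
        f"allele2={gm[2]:.4f} allele3={gm[3]:.4f}\n"
    )
    buf.write(
        "\n# Cumulative-logit fit\n"
        f"alpha1={fit.alpha1:.4f} alpha2={fit.alpha2:.4f} beta={fit.beta:.4f}\n"
        f"iterations={fit.n_iter} converged={fit.converged} "
        f"separated={fit.separated} "
        f"final_grad_norm={fit.final_grad_norm:.3e} loglik={fit.loglik:.4f}\n"
    )
    return buf.getvalue()
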
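"""Synthetic dissociation curves with known genotype.

Every pipeline stage is testable without instrument data: a target melting
curve is built from one or two Gaussian peaks at the allele melting
temperatures, integrated into a fluorescence trace (so that -dF/dT recovers
it up to discretisation), then degraded with linear baseline drift and
additive Gaussian noise on the fluorescence — where differentiation
amplifies it, as on a real instrument.

Defaults emulate the demonstration assay conditions: a 60-95 degC window
ramped at a 0.2 degC gradient, bell-shaped melting transitions of about
1 degC standard deviation, and a small subpopulation of heterozygotes whose
first-allele (lower-Tm) peak is weak — the discordance mode observed on
real Tm-shifted assays, where the weak A peak pushes the ratio x toward 1
and the het is miscalled as the B homozygote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .curves import DissociationCurve
from .errors import InvalidParamsError
from .peaks import SnpAssayDef

__all__ = ["SynthParams", "generate_well", "generate_panel", "demo_assays"]

DEFAULT_GRID = (60.0, 95.0, 0.2)


@dataclass(frozen=True)
class SynthParams:
    """Parameters for one synthetic well.

    Genotype forces the amplitudes: class 1 (AA) zeroes amp_b, class 3 (BB)
    zeroes amp_a, class 2 (AB) requires both positive.  A single Tm jitter
    draw shifts both peaks together (plate-level temperature offset).
    """

    assay: SnpAssayDef
    genotype: int
    amp_a: float = 2.0
    amp_b: float = 2.0
    peak_sigma: float = 1.0  # degC; bell width of the melting transition
    tm_jitter_sd: float = 0.3  # degC
    baseline_slope: float = -0.05  # fluorescence per degC
    noise_sd: float = 0.01  # fluorescence units, applied to F
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.genotype not in (1, 2, 3):
            raise InvalidParamsError(f"genotype must be 1, 2 or 3: {self.genotype}")
        if self.amp_a < 0 or self.amp_b < 0:
            raise InvalidParamsError("amplitudes must be >= 0")
        amp_a, amp_b = self.amp_a, self.amp_b
        if self.genotype == 1:
            amp_b = 0.0
        elif self.genotype == 3:
            amp_a = 0.0
        elif amp_a <= 0 or amp_b <= 0:
            raise InvalidParamsError("heterozygote requires both amplitudes > 0")
        object.__setattr__(self, "amp_a", amp_a)
        object.__setattr__(self, "amp_b", amp_b)
        start, stop, step = self.grid
        if step <= 0:
            raise InvalidParamsError(f"grid step must be > 0: {step}")
        if not (
            start < self.assay.tm_a - 3 * self.peak_sigma
            and stop > self.assay.tm_b + 3 * self.peak_sigma
        ):
            raise InvalidParamsError(
                f"grid ({start}, {stop}) must contain both peaks with a "
                f"3-sigma margin (Tm {self.assay.tm_a}/{self.assay.tm_b}, "
                f"sigma {self.peak_sigma})"
            )


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def generate_well(params: SynthParams) -> tuple[DissociationCurve, int]:
    """Simulate one well; deterministic given the seed.

    Returns the raw dissociation curve and the true genotype class.
    """
    rng = np.random.default_rng(params.seed)
    start, stop, step = params.grid
    t = np.arange(start, stop + step / 2, step)
    jitter = rng.normal(0.0, params.tm_jitter_sd) if params.tm_jitter_sd > 0 else 0.0
    m_target = params.amp_a * _gauss(
        t, params.assay.tm_a + jitter, params.peak_sigma
    ) + params.amp_b * _gauss(t, params.assay.tm_b + jitter, params.peak_sigma)
    f = 100.0 - cumulative_trapezoid(m_target, t, initial=0.0)
    f = f + params.baseline_slope * (t - t[0])
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    curve = DissociationCurve(
        temperatures=t,
        intensities=f,
        well_id=params.well_id,
        snp_id=params.assay.snp_id,
    )
    return curve, params.genotype


def generate_panel(
    assays: list[SnpAssayDef],
    n_per_genotype: int = 15,
    *,
    amp: float = 2.0,
    weak_het_fraction: float = 0.02,
    weak_shrink: float = 0.2,
    peak_sigma: float = 1.0,
    tm_jitter_sd: float = 0.3,
    baseline_slope: float = -0.05,
    noise_sd: float = 0.01,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    seed: int = 0,
) -> tuple[list[DissociationCurve], pd.DataFrame]:
    """Simulate a labelled panel spanning all genotypes for every assay.

    A fixed share ``weak_het_fraction`` of the heterozygous wells
    (``round(fraction * n_hets)`` wells, positions drawn at random) has its
    first-allele amplitude shrunk by ``weak_shrink``, exercising the
    weak-A-peak discordance mode.  The count is deterministic so the panel
    composition is a controlled condition rather than a binomial draw; the
    default share (2% of hets) keeps the failure rare, at roughly the
    prevalence seen in real panels.

    Returns
    -------
    curves : list of DissociationCurve
    truth : DataFrame with columns (well_id, snp_id, genotype)
    """
    if n_per_genotype < 1:
        raise InvalidParamsError("n_per_genotype must be >= 1")
    rng = np.random.default_rng(seed)

    specs = [
        (assay, genotype, i)
        for assay in assays
        for genotype in (1, 2, 3)
        for i in range(n_per_genotype)
    ]
    het_positions = [j for j, (_, g, _) in enumerate(specs) if g == 2]
    n_weak = round(weak_het_fraction * len(het_positions))
    weak = set(rng.choice(het_positions, size=n_weak, replace=False)) if n_weak else set()

    curves: list[DissociationCurve] = []
    records: list[dict] = []
    for j, (assay, genotype, i) in enumerate(specs):
        amp_a = amp * weak_shrink if j in weak else amp
        well_id = f"{assay.snp_id}-g{genotype}-w{i:03d}"
        params = SynthParams(
            assay=assay,
            genotype=genotype,
            amp_a=amp_a,
            amp_b=amp,
            peak_sigma=peak_sigma,
            tm_jitter_sd=tm_jitter_sd,
            baseline_slope=baseline_slope,
            noise_sd=noise_sd,
            grid=grid,
            seed=int(rng.integers(2**31)),
            well_id=well_id,
        )
        curve, g = generate_well(params)
        curves.append(curve)
        records.append({"well_id": well_id, "snp_id": assay.snp_id, "genotype": g})
    return curves, pd.DataFrame.from_records(records)


def demo_assays(n: int = 12) -> list[SnpAssayDef]:
    """A 12-SNP demonstration panel with staggered Tm pairs.

    Allele labels follow a typical mixed panel; theoretical Tm pairs are
    illustrative values with 3.5-5 degC shifts, the range Tm-shifted
    primer designs target.  All offsets are zero (the panel is simulated
    without SNP-specific signal bias).
    """
    labels = [
        ("T", "C"), ("G", "A"), ("A", "G"), ("C", "T"),
        ("C", "G"), ("A", "G"), ("G", "T"), ("T", "C"),
        ("T", "C"), ("G", "C"), ("A", "G"), ("G", "A"),
    ]
    assays = []
    for i in range(n):
        a, b = labels[i % len(labels)]
        tm_a = 74.0 + 1.0 * (i % 7)
        tm_b = tm_a + 3.5 + 0.25 * (i % 5)
        assays.append(
            SnpAssayDef(
                snp_id=f"SNP{i + 1}",
                tm_a=tm_a,
                tm_b=tm_b,
                allele_a=a,
                allele_b=b,
                delta=0.0,
            )
        )
    return assays
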
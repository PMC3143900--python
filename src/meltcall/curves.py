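"""Dissociation curves and their derivative melting curves.

A dissociation curve records the fluorescence F of a saturating
double-strand dye while the temperature T ramps up and the PCR duplex
denatures.  The melting curve is the negative first derivative
M = -dF/dT, on which melting transitions appear as peaks near the
duplex melting temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidCurveError

__all__ = ["DissociationCurve", "MeltingCurve", "melting_curve"]


@dataclass(frozen=True)
class DissociationCurve:
    """Raw fluorescence-vs-temperature samples for one reaction well.

    Parameters
    ----------
    temperatures : array-like of float
        Strictly increasing temperature grid in degrees Celsius, length >= 3.
    intensities : array-like of float
        Fluorescence (arbitrary units), same length as ``temperatures``.
    well_id, snp_id : str
        Opaque labels identifying the well and the assayed SNP.
    """

    temperatures: np.ndarray
    intensities: np.ndarray
    well_id: str = ""
    snp_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or t.shape != f.shape:
            raise InvalidCurveError(
                f"well {self.well_id!r}: temperatures and intensities must be "
                f"1-D and of equal length (got {t.shape} vs {f.shape})"
            )
        if t.size < 3:
            raise InvalidCurveError(
                f"well {self.well_id!r}: need at least 3 samples, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise InvalidCurveError(
                f"well {self.well_id!r}: temperatures must be strictly increasing"
            )
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "intensities", f)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class MeltingCurve:
    """Negative first derivative M(T) = -dF/dT, optionally smoothed.

    The grid is the same as the source dissociation curve's
    (central differences interior, one-sided at the two ends), so region
    lookups anchored at theoretical melting temperatures stay aligned.
    """

    temperatures: np.ndarray
    values: np.ndarray
    smoothing_sigma: float | None = None
    well_id: str = ""
    snp_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise InvalidCurveError("temperatures and values must match in length")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.temperatures.size

    def mean_height(self) -> float:
        """Arithmetic mean of M over the full recorded grid."""
        return float(np.mean(self.values))


def melting_curve(
    curve: DissociationCurve, smoothing_sigma: float | None = None
) -> MeltingCurve:
    """Differentiate a dissociation curve into a melting curve.

    M = -dF/dT is computed with central differences on interior points and
    one-sided differences at the two ends, keeping the original grid length.
    Non-uniform grids are handled by dividing by the local temperature step.

    Parameters
    ----------
    curve : DissociationCurve
    smoothing_sigma : float or None
        Standard deviation, in degrees Celsius, of an optional Gaussian
        kernel convolved with M after differentiation (converted to samples
        using the median grid step; reflective edge padding). ``None`` or 0
        disables smoothing, the default: the raw derivative is usually
        clean enough on 0.2 C instrument gradients.

    Returns
    -------
    MeltingCurve

    Raises
    ------
    InvalidCurveError
        If the curve has fewer than 3 samples or a non-monotone grid
        (raised when the DissociationCurve is constructed).
    """
    if smoothing_sigma is not None and smoothing_sigma < 0:
        raise ValueError(f"smoothing_sigma must be >= 0, got {smoothing_sigma}")
    t = curve.temperatures
    m = -np.gradient(curve.intensities, t)
    if smoothing_sigma:
        step = float(np.median(np.diff(t)))
        m = gaussian_filter1d(m, sigma=smoothing_sigma / step, mode="reflect")
    return MeltingCurve(
        temperatures=t,
        values=m,
        smoothing_sigma=smoothing_sigma or None,
        well_id=curve.well_id,
        snp_id=curve.snp_id,
    )
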
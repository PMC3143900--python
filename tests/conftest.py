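import numpy as np
import pytest

from meltcall import MeltingCurve, SnpAssayDef, get_preset


@pytest.fixture
def assay() -> SnpAssayDef:
    """A typical Tm-shifted assay: 4 degC shift between allele products."""
    return SnpAssayDef(snp_id="SNPX", tm_a=80.0, tm_b=84.0, allele_a="C", allele_b="G")


@pytest.fixture
def preset_model():
    return get_preset("paper-2011")


@pytest.fixture
def grid() -> np.ndarray:
    return np.arange(60.0, 95.0 + 0.1, 0.2)


@pytest.fixture
def make_melting_curve(grid):
    """Build a MeltingCurve from a sum of Gaussian bumps on the default grid."""

    def _make(bumps: list[tuple[float, float]], sigma: float = 1.0, offset: float = 0.0):
        values = np.full_like(grid, offset)
        for center, amp in bumps:
            values = values + amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        return MeltingCurve(temperatures=grid, values=values)

    return _make
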
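import numpy as np
import pytest
from scipy.special import expit

from meltcall import (
    LabeledWell,
    TrainingDataError,
    fit_offsets,
    fit_ordinal,
    grand_means,
)
from meltcall.estimators import round_half_away
from meltcall.train import _calibrator


def wells_from(snp_class_values: dict[str, dict[int, list[float]]]):
    return [
        LabeledWell(snp_id=snp, x=x, genotype=g)
        for snp, classes in snp_class_values.items()
        for g, xs in classes.items()
        for x in xs
    ]


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.07, 0.1), (-0.04, 0.0), (0.05, 0.1), (-0.05, -0.1), (0.0, 0.0),
         (0.14, 0.1), (-0.15, -0.2)],
    )
    def test_half_away_from_zero_one_decimal(self, value, expected):
        r = round_half_away(value, 1)
        assert r == expected
        assert not np.signbit(r) or r != 0.0  # -0.0 normalised


class TestGrandMeans:
    def test_mean_of_per_snp_means(self):
        wells = wells_from(
            {
                "s1": {1: [0.0], 2: [0.3, 0.5], 3: [1.0]},
                "s2": {1: [0.1], 2: [0.6], 3: [0.9]},
            }
        )
        gm = grand_means(wells)
        assert gm[2] == pytest.approx(0.5)  # mean of 0.4 and 0.6
        assert gm[1] == pytest.approx(0.05)
        assert gm[3] == pytest.approx(0.95)

    def test_single_snp_reduces_to_class_means(self):
        wells = wells_from({"s1": {1: [0.0, 0.1], 2: [0.5], 3: [0.9]}})
        gm = grand_means(wells)
        assert gm == {1: pytest.approx(0.05), 2: 0.5, 3: 0.9}

    def test_class_absent_everywhere_is_an_error(self):
        wells = wells_from({"s1": {1: [0.0], 3: [1.0]}})
        with pytest.raises(TrainingDataError, match="class 2"):
            grand_means(wells)

    def test_class_missing_in_one_snp_is_tolerated(self):
        wells = wells_from(
            {
                "s1": {1: [0.0], 2: [0.5], 3: [1.0]},
                "s2": {1: [0.2], 3: [0.8]},  # no heterozygote observed
            }
        )
        gm = grand_means(wells)
        assert gm[2] == pytest.approx(0.5)
        assert gm[1] == pytest.approx(0.1)


class TestFitOffsets:
    def test_zero_when_class_means_match_grand_means(self):
        wells = wells_from(
            {
                "s1": {1: [0.05], 2: [0.5], 3: [0.95]},
                "s2": {1: [0.05], 2: [0.5], 3: [0.95]},
            }
        )
        assert fit_offsets(wells) == {"s1": 0.0, "s2": 0.0}

    def test_systematic_shift_becomes_the_offset(self):
        # s2 shifted +0.2 in every class against two anchor SNPs: its
        # deviation from the grand means is 2/3 * 0.2 ~ 0.133 -> rounds to 0.1
        base = {1: [0.05], 2: [0.5], 3: [0.8]}
        shifted = {k: [v[0] + 0.2] for k, v in base.items()}
        wells = wells_from({"s1": base, "s2": base, "s3": shifted})
        offsets = fit_offsets(wells)
        assert offsets["s3"] == pytest.approx(0.1)
        assert offsets["s1"] == offsets["s2"] == pytest.approx(-0.1)

    def test_offsets_are_one_decimal(self):
        wells = wells_from(
            {
                "s1": {1: [0.03], 2: [0.52], 3: [0.97]},
                "s2": {1: [0.11], 2: [0.44], 3: [0.88]},
            }
        )
        for delta in fit_offsets(wells).values():
            assert delta == round(delta, 1)

    def test_shift_equivariance_of_unrounded_deviations(self):
        """Adding c to every x of one SNP moves its unrounded deviation by
        c * (K-1)/K (K SNPs share the grand mean) and the others' by -c/K."""
        base = {
            "s1": {1: [0.05], 2: [0.5], 3: [0.85]},
            "s2": {1: [0.05], 2: [0.5], 3: [0.85]},
            "s3": {1: [0.05], 2: [0.5], 3: [0.85]},
        }
        c = 0.12
        shifted = {
            snp: {g: [x + (c if snp == "s2" else 0.0) for x in xs] for g, xs in cl.items()}
            for snp, cl in base.items()
        }
        dev0 = _calibrator(wells_from(base)).deviations_
        dev1 = _calibrator(wells_from(shifted)).deviations_
        k = 3
        assert dev1["s2"] - dev0["s2"] == pytest.approx(c * (k - 1) / k)
        assert dev1["s1"] - dev0["s1"] == pytest.approx(-c / k)
        assert dev1["s3"] - dev0["s3"] == pytest.approx(-c / k)


def simulate_ordinal(alpha1, alpha2, beta, x, rng):
    p1 = expit(alpha1 - beta * x)
    c12 = expit(alpha2 - beta * x)
    u = rng.random(x.size)
    return np.where(u < p1, 1, np.where(u < c12, 2, 3))


class TestFitOrdinal:
    def test_well_conditioned_recovery_within_10_percent(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(-3.0, 3.0, 2000)
        y = simulate_ordinal(-1.0, 1.0, 2.0, x, rng)
        from meltcall import OrdinalGenotypeCaller

        est = OrdinalGenotypeCaller().fit(x, y)
        assert est.converged_ and not est.separated_
        assert est.alpha1_ == pytest.approx(-1.0, rel=0.10)
        assert est.alpha2_ == pytest.approx(1.0, rel=0.10)
        assert est.beta_ == pytest.approx(2.0, rel=0.10)

    def test_matches_statsmodels_ordered_model(self):
        """Independent cross-check of the Newton-Raphson fit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        from meltcall import OrdinalGenotypeCaller

        rng = np.random.default_rng(7)
        x = rng.uniform(-2.0, 2.0, 800)
        y = simulate_ordinal(-0.5, 0.8, 1.5, x, rng)
        est = OrdinalGenotypeCaller().fit(x, y)
        res = OrderedModel(y, x[:, None], distr="logit").fit(
            method="bfgs", disp=False
        )
        thresholds = res.model.transform_threshold_params(res.params)
        assert est.alpha1_ == pytest.approx(thresholds[1], abs=1e-3)
        assert est.alpha2_ == pytest.approx(thresholds[2], abs=1e-3)
        assert est.beta_ == pytest.approx(res.params[0], abs=1e-3)

    def test_steep_regime_recovers_or_reports_separation(self):
        """Cluster-centred ratios with steep true coefficients: the fit
        either lands within 20% or honestly flags (near-)separation."""
        from meltcall import OrdinalGenotypeCaller

        rng = np.random.default_rng(1)
        centers = rng.choice([0.0, 0.5, 1.0], 500)
        x = centers + rng.uniform(-0.15, 0.15, 500)
        y = simulate_ordinal(15.3, 35.8, 51.0, x, rng)
        est = OrdinalGenotypeCaller().fit(x, y)
        if not est.separated_:
            assert est.alpha1_ == pytest.approx(15.3, rel=0.20)
            assert est.alpha2_ == pytest.approx(35.8, rel=0.20)
            assert est.beta_ == pytest.approx(51.0, rel=0.20)

    def test_loglik_monotone_along_iterations(self):
        from meltcall import OrdinalGenotypeCaller

        rng = np.random.default_rng(3)
        x = rng.uniform(-3.0, 3.0, 500)
        y = simulate_ordinal(-1.0, 1.0, 2.0, x, rng)
        est = OrdinalGenotypeCaller().fit(x, y)
        assert np.all(np.diff(est.loglik_path_) >= -1e-9)

    def test_perfect_separation_capped_with_warning(self):
        from meltcall import OrdinalGenotypeCaller

        x = np.concatenate([np.zeros(30), np.full(30, 0.5), np.ones(30)])
        y = np.repeat([1, 2, 3], 30)
        with pytest.warns(RuntimeWarning, match="separat"):
            est = OrdinalGenotypeCaller().fit(x, y)
        assert est.separated_
        assert np.max(np.abs([est.alpha1_, est.alpha2_, est.beta_])) <= 500.0 + 1e-3

    def test_two_class_input_rejected(self):
        wells = [LabeledWell("s", 0.1, 1), LabeledWell("s", 0.9, 3)]
        with pytest.raises(TrainingDataError, match="class"):
            fit_ordinal(wells, {"s": 0.0})

    def test_offsets_applied_before_fitting(self):
        """Shifting one SNP's x and giving it the matching delta must yield
        the same fit as the unshifted data with zero offsets."""
        rng = np.random.default_rng(11)
        x = np.clip(rng.uniform(0.0, 1.0, 300), 0, 1)
        y = simulate_ordinal(2.0, 6.0, 8.0, x, rng)
        base = [LabeledWell("a", float(xi), int(yi)) for xi, yi in zip(x, y)]
        shifted = [
            LabeledWell("a", float(np.clip(xi + 0.1, 0, 1)), int(yi))
            for xi, yi in zip(x, y)
            if 0.0 <= xi + 0.1 <= 1.0
        ]
        kept = [w for w, xi in zip(base, x) if 0.0 <= xi + 0.1 <= 1.0]
        fit0 = fit_ordinal(kept, {"a": 0.0})
        fit1 = fit_ordinal(shifted, {"a": 0.1})
        assert fit1.alpha1 == pytest.approx(fit0.alpha1, abs=1e-6)
        assert fit1.beta == pytest.approx(fit0.beta, abs=1e-6)
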
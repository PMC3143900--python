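"""scikit-learn style estimators for calibration and ordinal genotype calling.

Two estimators cover the trainable parts of the pipeline:

* :class:`SnpOffsetCalibrator` — a transformer that learns the SNP-specific
  offsets delta aligning each SNP's signal-ratio distribution with the
  cross-SNP grand means, and transforms raw ratios x into adjusted ratios
  X = x - delta.
* :class:`OrdinalGenotypeCaller` — a classifier fitting the
  proportional-odds (cumulative logit) model of genotype class on X by
  maximum likelihood (Newton-Raphson with step-halving), and predicting
  calls with the probability-margin reject option.

The module-level functions in :mod:`meltcall.train` are thin wrappers over
these estimators.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import TrainingDataError
from .model import (
    AlleleProbabilities,
    Call,
    OrdinalCallModel,
    allele_probabilities,
    call_base,
)

__all__ = ["OrdinalGenotypeCaller", "SnpOffsetCalibrator", "round_half_away"]

CLASSES = (1, 2, 3)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (0.05 -> 0.1, -0.05 -> -0.1)."""
    scale = 10.0**decimals
    r = math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale
    return r + 0.0  # normalise -0.0


def _loglik_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Log-likelihood and analytic gradient of the cumulative-logit model.

    Parameterisation: logit P(Z<=1) = a1 - b*x, logit P(Z<=2) = a2 - b*x.
    Returns (-inf, None) for infeasible theta (a1 >= a2 or zero-probability
    observation), which the line search treats as a rejected step.
    """
    a1, a2, b = theta
    if a1 >= a2:
        return -np.inf, None
    f1 = expit(a1 - b * x)
    f2 = expit(a2 - b * x)
    m1, m2, m3 = y == 1, y == 2, y == 3
    p2 = f2[m2] - f1[m2]
    with np.errstate(divide="ignore"):
        ll = (
            np.sum(np.log(f1[m1]))
            + np.sum(np.log(p2))
            + np.sum(np.log1p(-f2[m3]))
        )
    if not np.isfinite(ll):
        return -np.inf, None
    g1_2 = f1[m2] * (1 - f1[m2])
    g2_2 = f2[m2] * (1 - f2[m2])
    grad = np.array(
        [
            np.sum(1 - f1[m1]) - np.sum(g1_2 / p2),
            np.sum(g2_2 / p2) - np.sum(f2[m3]),
            (
                -np.sum(x[m1] * (1 - f1[m1]))
                - np.sum(x[m2] * (g2_2 - g1_2) / p2)
                + np.sum(x[m3] * f2[m3])
            ),
        ]
    )
    return float(ll), grad


def _fd_hessian(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Hessian by central differences of the analytic gradient."""
    n = theta.size
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    hess = np.empty((n, n))
    for j in range(n):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _loglik_grad(tp, x, y)
        _, gm = _loglik_grad(tm, x, y)
        if gp is None or gm is None:
            # boundary of the feasible region; fall back to one-sided
            _, g0 = _loglik_grad(theta, x, y)
            side = gp if gp is not None else gm
            sign = 1.0 if gp is not None else -1.0
            hess[:, j] = sign * (side - g0) / h[j]
        else:
            hess[:, j] = (gp - gm) / (2 * h[j])
    return (hess + hess.T) / 2


class OrdinalGenotypeCaller(ClassifierMixin, BaseEstimator):
    """Proportional-odds genotype caller with a no-call margin.

    Fits logit P(Z<=k) = alpha_k - beta*X for ordered genotype classes
    Z in {1 (AA), 2 (AB), 3 (BB)} on the adjusted signal ratio X, by
    Newton-Raphson maximum likelihood with step-halving (monotone in the
    log-likelihood).  Perfect or near-perfect class separation makes the
    likelihood unbounded; divergence is detected by a coefficient cap and
    reported via ``separated_`` and a warning rather than an error.

    Parameters
    ----------
    rho : float, default=0.05
        Probability margin of the reject option: a class is called only if
        its probability exceeds both others by strictly more than rho.
        With rho=0 every well gets the argmax class.
    coef_cap : float, default=500.0
        Absolute bound on any coefficient; reaching it flags separation.
    max_iter : int, default=100
    gtol : float, default=1e-8
        Convergence threshold on the max-norm of the gradient.

    Attributes
    ----------
    alpha1_, alpha2_, beta_ : float
        Fitted coefficients (alpha1_ < alpha2_, beta_ > 0 for ordered data).
    n_iter_ : int
    converged_ : bool
    separated_ : bool
        True when the coefficient cap was hit (unbounded likelihood).
    final_grad_norm_ : float
    loglik_path_ : list of float
        Log-likelihood at each accepted iterate (non-decreasing).
    classes_ : ndarray of shape (3,)
    """

    def __init__(
        self,
        rho: float = 0.05,
        coef_cap: float = 500.0,
        max_iter: int = 100,
        gtol: float = 1e-8,
    ) -> None:
        self.rho = rho
        self.coef_cap = coef_cap
        self.max_iter = max_iter
        self.gtol = gtol

    # -- construction from known coefficients (e.g. the published preset) --

    @classmethod
    def from_coefficients(
        cls, alpha1: float, alpha2: float, beta: float, rho: float = 0.05
    ) -> "OrdinalGenotypeCaller":
        """Build an already-usable caller from known coefficients."""
        est = cls(rho=rho)
        est.alpha1_ = float(alpha1)
        est.alpha2_ = float(alpha2)
        est.beta_ = float(beta)
        est.classes_ = np.array(CLASSES)
        est.n_iter_ = 0
        est.converged_ = True
        est.separated_ = False
        est.final_grad_norm_ = float("nan")
        est.loglik_path_ = []
        return est

    @classmethod
    def from_model(cls, model: OrdinalCallModel) -> "OrdinalGenotypeCaller":
        return cls.from_coefficients(model.alpha1, model.alpha2, model.beta, model.rho)

    def to_model(self, rho: float | None = None) -> OrdinalCallModel:
        check_is_fitted(self, "beta_")
        return OrdinalCallModel(
            alpha1=self.alpha1_,
            alpha2=self.alpha2_,
            beta=self.beta_,
            rho=self.rho if rho is None else rho,
        )

    # -- fitting --

    @staticmethod
    def _validate_xy(X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=int).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same number of samples")
        present = set(np.unique(y))
        if not present <= set(CLASSES):
            raise TrainingDataError(
                f"genotype labels must be in {CLASSES}, got {sorted(present)}"
            )
        missing = set(CLASSES) - present
        if missing:
            raise TrainingDataError(
                f"genotype class(es) {sorted(missing)} absent from training data; "
                "all three classes are required to fit the cumulative-logit model"
            )
        return x, y

    def fit(self, X, y) -> "OrdinalGenotypeCaller":
        """Maximum-likelihood fit on adjusted ratios X and genotype classes y.

        Parameters
        ----------
        X : array-like of shape (n_samples,) or (n_samples, 1)
            Adjusted signal-strength ratios.
        y : array-like of shape (n_samples,)
            Known genotype classes in {1, 2, 3} (all three must occur).
        """
        x, y = self._validate_xy(X, y)
        n = x.size

        # init: alphas from empirical cumulative class frequencies, beta = 0
        q1 = np.clip(np.mean(y == 1), 1 / (n + 1), n / (n + 1))
        q12 = np.clip(np.mean(y <= 2), 1 / (n + 1), n / (n + 1))
        if q12 <= q1:
            q12 = min(q1 + 1 / (n + 1), n / (n + 1) + 1e-9)
        theta = np.array([logit(q1), logit(q12), 0.0])

        ll, grad = _loglik_grad(theta, x, y)
        path = [ll]
        separated = False
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.gtol:
                converged = True
                it -= 1
                break
            hess = _fd_hessian(theta, x, y)
            try:
                step = np.linalg.solve(hess, -grad)
            except np.linalg.LinAlgError:
                step = grad / max(1.0, np.max(np.abs(grad)))
            if float(step @ grad) <= 0:  # not an ascent direction
                step = grad / max(1.0, np.max(np.abs(grad)))
            t = 1.0
            new_ll, new_grad = _loglik_grad(theta + t * step, x, y)
            while new_ll < ll and t > 1e-12:
                t /= 2
                new_ll, new_grad = _loglik_grad(theta + t * step, x, y)
            if new_ll < ll:
                break  # no ascent possible along this direction
            theta = theta + t * step
            ll, grad = new_ll, new_grad
            path.append(ll)
            if np.max(np.abs(theta)) > self.coef_cap:
                separated = True
                theta = np.clip(theta, -self.coef_cap, self.coef_cap)
                if theta[0] >= theta[1]:
                    theta[1] = theta[0] + 1e-6
                ll, grad = _loglik_grad(theta, x, y)
                warnings.warn(
                    "cumulative-logit fit diverged (coefficient cap "
                    f"{self.coef_cap} reached): classes are (near-)separated "
                    "in X; returning the capped fit",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
        else:
            it = self.max_iter

        if not separated and not converged:
            converged = bool(np.max(np.abs(grad)) < self.gtol)

        # a log-likelihood plateau at ~0 means every observation is fit
        # perfectly: the supremum of a separated likelihood, reached
        # numerically before the coefficient cap
        if not separated and ll > -1e-3:
            separated = True
            warnings.warn(
                "cumulative-logit likelihood reached its separated-data "
                f"supremum (loglik {ll:.2e}): classes are (near-)separated "
                "in X; coefficients are not identified",
                RuntimeWarning,
                stacklevel=2,
            )

        self.alpha1_, self.alpha2_, self.beta_ = (float(v) for v in theta)
        self.n_iter_ = it
        self.converged_ = converged
        self.separated_ = separated
        self.final_grad_norm_ = float(np.max(np.abs(grad)))
        self.loglik_path_ = path
        self.loglik_ = float(ll)
        self.classes_ = np.array(CLASSES)
        return self

    # -- prediction --

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities (p1, p2, p3) at each adjusted ratio."""
        check_is_fitted(self, "beta_")
        x = np.asarray(X, dtype=float).reshape(-1)
        p1 = expit(self.alpha1_ - self.beta_ * x)
        c12 = expit(self.alpha2_ - self.beta_ * x)
        out = np.column_stack([p1, np.maximum(c12 - p1, 0.0), 1.0 - c12])
        return out

    def predict(self, X) -> np.ndarray:
        """Margin-rule genotype calls: 1, 2 or 3, or 0 for a no-call.

        The reject option is intrinsic to the method, so ``predict``
        applies it; use ``rho=0`` for plain argmax behaviour.
        """
        proba = self.predict_proba(X)
        calls = np.zeros(proba.shape[0], dtype=int)
        for i, row in enumerate(proba):
            c = call_base(
                AlleleProbabilities(p1=row[0], p2=row[1], p3=row[2]), self.rho
            )
            calls[i] = c.ordinal or 0
        return calls

    def call(self, x_adjusted: float) -> Call:
        """Single-value convenience: margin-rule call at one adjusted ratio."""
        check_is_fitted(self, "beta_")
        probs = allele_probabilities(self.to_model(), x_adjusted)
        return call_base(probs, self.rho)


class SnpOffsetCalibrator(TransformerMixin, BaseEstimator):
    """Learn SNP-specific ratio offsets and apply X = x - delta.

    For each genotype class the per-SNP mean of x is averaged over SNPs
    (an unweighted mean of means) to give the grand means <x>.  Each SNP's
    per-class deviations from the grand means are then averaged over the
    classes it has, and rounded half-away-from-zero to ``decimals`` digits,
    giving its offset delta.  Low-resolution rounding deliberately keeps
    most offsets at zero so one shared calling model covers most SNPs.

    Parameters
    ----------
    decimals : int, default=1
        Rounding resolution of the stored offsets.

    Attributes
    ----------
    grand_means_ : dict class -> float
    class_means_ : dict snp_id -> dict class -> float
    deviations_ : dict snp_id -> float
        Unrounded mean-of-deviations per SNP.
    offsets_ : dict snp_id -> float
        Rounded offsets delta.
    """

    def __init__(self, decimals: int = 1) -> None:
        self.decimals = decimals

    @staticmethod
    def _split_X(X):
        """Accept a 2-column structure (snp_id, x) as DataFrame or array."""
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            if not {"snp_id", "x"} <= set(X.columns):
                raise ValueError("DataFrame input needs columns 'snp_id' and 'x'")
            return X["snp_id"].to_numpy(), X["x"].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=object)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("array input must have two columns: (snp_id, x)")
        return arr[:, 0], arr[:, 1].astype(float)

    def fit(self, X, y) -> "SnpOffsetCalibrator":
        """Learn grand means and per-SNP offsets from labelled ratios.

        Parameters
        ----------
        X : DataFrame with columns (snp_id, x) or (n, 2) array
        y : genotype classes in {1, 2, 3}
        """
        snp_ids, x = self._split_X(X)
        y = np.asarray(y, dtype=int).reshape(-1)
        if np.any(~np.isin(y, CLASSES)):
            raise TrainingDataError("genotype labels must be in {1, 2, 3}")
        if np.any((x < 0) | (x > 1)):
            raise TrainingDataError("signal ratios x must lie in [0, 1]")

        snps = list(dict.fromkeys(snp_ids))  # stable order of appearance
        class_means: dict[str, dict[int, float]] = {}
        for snp in snps:
            sel = snp_ids == snp
            means = {
                k: float(np.mean(x[sel & (y == k)]))
                for k in CLASSES
                if np.any(sel & (y == k))
            }
            if means:
                class_means[snp] = means
            else:
                warnings.warn(f"SNP {snp!r} has no wells; excluded", stacklevel=2)

        grand: dict[int, float] = {}
        for k in CLASSES:
            vals = [m[k] for m in class_means.values() if k in m]
            if not vals:
                raise TrainingDataError(
                    f"genotype class {k} is absent from every SNP; grand mean "
                    "undefined"
                )
            grand[k] = float(np.mean(vals))

        deviations = {
            snp: float(np.mean([m[k] - grand[k] for k in m]))
            for snp, m in class_means.items()
        }
        self.grand_means_ = grand
        self.class_means_ = class_means
        self.deviations_ = deviations
        self.offsets_ = {
            snp: round_half_away(d, self.decimals) for snp, d in deviations.items()
        }
        return self

    def transform(self, X) -> np.ndarray:
        """Adjusted ratios X = x - delta; unseen SNPs get delta = 0."""
        check_is_fitted(self, "offsets_")
        snp_ids, x = self._split_X(X)
        unseen = sorted({s for s in snp_ids if s not in self.offsets_})
        if unseen:
            warnings.warn(
                f"SNP(s) {unseen} not seen during fit; using offset 0", stacklevel=2
            )
        deltas = np.array([self.offsets_.get(s, 0.0) for s in snp_ids])
        return x - deltas
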
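"""Two-component Gaussian mixture fit to a kernel density estimate.

The over-expression frequency of a bimodally expressed gene is estimated in
two stages, mirroring classic microarray practice: (1) a Gaussian-kernel
density estimate of the per-sample log2 expression values; (2) a nonlinear
least-squares fit of a two-component normal mixture

    f(x) = p N(x; mu1, sigma1) + (1 - p) N(x; mu2, sigma2)

to the estimated density curve, where ``p`` is the fraction of tumors
over-expressing the gene, ``mu1 > mu2`` are the high/low component means,
and the default ("equal_variance") variant constrains sigma1 = sigma2.
Samples are then classified high/low at the expression value where the two
weighted component densities cross.

Fitting the KDE curve (rather than maximizing the sample likelihood) is a
deliberate choice; an EM maximum-likelihood fit can be used as an external
cross-check but is not what this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import optimize
from scipy.stats import norm

EQUAL_VARIANCE = "equal_variance"
UNEQUAL_VARIANCE = "unequal_variance"

_MAX_ITER = 500
_XTOL = 1e-8


class InsufficientDataError(ValueError):
    """Too few finite values to estimate a density."""


class DegenerateInputError(ValueError):
    """Zero-variance input; no density to estimate."""


class FitFailureError(RuntimeError):
    """Mixture fit failed to converge even after the grid-search fallback."""

    def __init__(self, message: str, residual_ss: float | None = None):
        super().__init__(message)
        self.residual_ss = residual_ss


@dataclass
class DensityCurve:
    """Kernel density estimate on an equally spaced grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_samples: int

    @property
    def n_points(self) -> int:
        return self.grid.size

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class BimodalFit:
    """Fitted mixture parameters and the derived high/low threshold.

    ``p`` is the mixing weight of the high component, i.e. the estimated
    frequency of over-expressing tumors.
    """

    variant: str
    p: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    residual_ss: float
    converged: bool
    n_samples: int
    classification_threshold: float

    @property
    def sigma(self) -> float:
        """Common SD (equal-variance variant only)."""
        return self.sigma1

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "p": self.p,
            "mu1": self.mu1,
            "mu2": self.mu2,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "residual_ss": self.residual_ss,
            "threshold": self.classification_threshold,
            "n": self.n_samples,
        }


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman rule-of-thumb: 0.9 min(sd, IQR/1.34) n^(-1/5).

    Matches the default bandwidth selector of the classic density routine
    this estimator replicates.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateInputError("zero spread; cannot select a bandwidth")
    return 0.9 * spread * n ** (-0.2)


def estimate_density(values, n_grid: int = 512, bandwidth: float | None = None
                     ) -> DensityCurve:
    """Gaussian-kernel KDE on an equally spaced grid.

    The grid spans [min - 3 bw, max + 3 bw]; default bandwidth is Silverman's
    rule of thumb. Requires at least 10 finite values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise InsufficientDataError(
            f"need >= 10 finite values for density estimation, got {values.size}")
    if values.std() == 0:
        raise DegenerateInputError("constant input has no density estimate")
    bw = float(bandwidth) if bandwidth is not None else silverman_bandwidth(values)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    # mean of kernel densities; (n_grid x n) is small at the sizes used here
    z = (grid[:, None] - values[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bw * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=bw,
                        n_samples=int(values.size))


def mixture_density(x, p: float, mu1: float, mu2: float,
                    sigma1: float, sigma2: float | None = None) -> np.ndarray:
    """Two-component normal mixture density; sigma2 defaults to sigma1."""
    if sigma2 is None:
        sigma2 = sigma1
    x = np.asarray(x, dtype=float)
    return p * norm.pdf(x, mu1, sigma1) + (1.0 - p) * norm.pdf(x, mu2, sigma2)


def _pack(p, mu1, mu2, s1, s2, variant):
    # p on logit scale, SDs on log scale: keeps the solver in the valid region
    eps = 1e-9
    p = min(max(p, eps), 1 - eps)
    theta = [np.log(p / (1 - p)), mu1, mu2, np.log(s1)]
    if variant == UNEQUAL_VARIANCE:
        theta.append(np.log(s2))
    return np.array(theta)


def _unpack(theta, variant):
    p = 1.0 / (1.0 + np.exp(-theta[0]))
    mu1, mu2 = theta[1], theta[2]
    s1 = np.exp(theta[3])
    s2 = np.exp(theta[4]) if variant == UNEQUAL_VARIANCE else s1
    return p, mu1, mu2, s1, s2


def _normalize_labels(p, mu1, mu2, s1, s2):
    """Relabel so mu1 is the high component and p its weight."""
    if mu1 < mu2:
        return 1.0 - p, mu2, mu1, s2, s1
    return p, mu1, mu2, s1, s2


def classification_threshold(p, mu1, mu2, sigma1, sigma2) -> float:
    """Expression value where the weighted component densities are equal.

    Solved between mu2 and mu1; equivalent to a posterior-probability 0.5
    boundary under the fitted mixture. Falls back to the midpoint when no
    crossing exists inside (mu2, mu1) (extreme weights or heavy overlap).
    """
    if mu1 <= mu2:
        raise ValueError("requires mu1 > mu2")
    p = min(max(p, 1e-12), 1 - 1e-12)

    def g(x):
        return (np.log(p) + norm.logpdf(x, mu1, sigma1)
                - np.log1p(-p) - norm.logpdf(x, mu2, sigma2))

    lo, hi = mu2, mu1
    if g(lo) < 0 < g(hi):
        return float(optimize.brentq(g, lo, hi, xtol=1e-12))
    return float(0.5 * (mu1 + mu2))


def _default_starts(curve: DensityCurve) -> tuple:
    """Start values from a 2-quantile split of the density mass."""
    w = curve.density / curve.density.sum()
    cdf = np.cumsum(w)
    mu_lo = float(np.interp(0.25, cdf, curve.grid))
    mu_hi = float(np.interp(0.75, cdf, curve.grid))
    mean = float((w * curve.grid).sum())
    sd = float(np.sqrt((w * (curve.grid - mean) ** 2).sum()))
    pooled = max(sd / 2.0, 1e-3)
    return 0.5, mu_hi, mu_lo, pooled, pooled


def _solve(curve: DensityCurve, variant: str, start: tuple):
    theta0 = _pack(*start, variant)

    def residuals(theta):
        p, mu1, mu2, s1, s2 = _unpack(theta, variant)
        return curve.density - mixture_density(curve.grid, p, mu1, mu2, s1, s2)

    res = optimize.least_squares(residuals, theta0, method="lm",
                                 xtol=_XTOL, ftol=_XTOL, max_nfev=_MAX_ITER * 6)
    p, mu1, mu2, s1, s2 = _unpack(res.x, variant)
    ss = float(np.sum(res.fun ** 2))
    ok = bool(res.success) and np.isfinite(ss)
    return (p, mu1, mu2, s1, s2), ss, ok


def fit_bimodal(curve: DensityCurve, variant: str = EQUAL_VARIANCE,
                starts: tuple | None = None) -> BimodalFit:
    """Nonlinear least-squares fit of the mixture to a density curve.

    Default starts come from a 2-quantile split of the density mass
    (component means at the 25th/75th mass percentiles, pooled spread for the
    SDs, p = 0.5); when the first solve fails, a coarse grid of 27 start
    combinations is searched. Component labels are normalized post-fit so
    that mu1 is always the high-expression component.
    """
    if variant not in (EQUAL_VARIANCE, UNEQUAL_VARIANCE):
        raise ValueError(f"unknown variant {variant!r}")
    start = tuple(starts) if starts is not None else _default_starts(curve)
    best_params, best_ss, ok = None, np.inf, False
    try:
        params, ss, ok = _solve(curve, variant, start)
        best_params, best_ss = params, ss
    except Exception:
        ok = False
    if not ok:
        # coarse 3x3x3 grid over (p, mean split, sd scale)
        p0, mu_hi0, mu_lo0, s0, _ = _default_starts(curve)
        span = max(mu_hi0 - mu_lo0, s0)
        center = 0.5 * (mu_hi0 + mu_lo0)
        for pp, frac, scale in product((0.3, 0.5, 0.7),
                                       (0.5, 1.0, 1.5),
                                       (0.5, 1.0, 2.0)):
            cand = (pp, center + frac * span / 2, center - frac * span / 2,
                    s0 * scale, s0 * scale)
            try:
                params, ss, good = _solve(curve, variant, cand)
            except Exception:
                continue
            if good and ss < best_ss:
                best_params, best_ss, ok = params, ss, True
        if not ok:
            raise FitFailureError("mixture NLS did not converge after fallback "
                                  "grid search", residual_ss=best_ss)
    p, mu1, mu2, s1, s2 = _normalize_labels(*best_params)
    thr = classification_threshold(p, mu1, mu2, s1, s2) if mu1 > mu2 \
        else float(0.5 * (mu1 + mu2))
    return BimodalFit(variant=variant, p=float(p), mu1=float(mu1), mu2=float(mu2),
                      sigma1=float(s1), sigma2=float(s2), residual_ss=best_ss,
                      converged=True, n_samples=curve.n_samples,
                      classification_threshold=thr)


def select_variant(curve: DensityCurve, improvement: float = 0.2) -> BimodalFit:
    """Fit both variants; keep equal-variance unless the unequal-variance fit
    cuts residual SS by more than ``improvement`` (default 20%).

    Both residuals are recorded on the returned fit (``residuals_both``
    attribute) for diagnostics.
    """
    eq_fit = eq_err = uneq_fit = uneq_err = None
    try:
        eq_fit = fit_bimodal(curve, EQUAL_VARIANCE)
    except FitFailureError as e:
        eq_err = e
    try:
        uneq_fit = fit_bimodal(curve, UNEQUAL_VARIANCE)
    except FitFailureError as e:
        uneq_err = e
    if eq_fit is None and uneq_fit is None:
        raise FitFailureError(f"both variants failed: {eq_err}; {uneq_err}")
    # scale floor: when the equal-variance fit is already essentially exact,
    # a relative comparison of two near-zero residuals is noise
    floor = 1e-12 * float(np.sum(curve.density ** 2))
    if eq_fit is None:
        chosen = uneq_fit
    elif uneq_fit is None or eq_fit.residual_ss <= floor:
        chosen = eq_fit
    elif uneq_fit.residual_ss < (1.0 - improvement) * eq_fit.residual_ss:
        chosen = uneq_fit
    else:
        chosen = eq_fit
    chosen.residuals_both = {  # type: ignore[attr-defined]
        EQUAL_VARIANCE: None if eq_fit is None else eq_fit.residual_ss,
        UNEQUAL_VARIANCE: None if uneq_fit is None else uneq_fit.residual_ss,
    }
    return chosen


def classify_samples(fit: BimodalFit, values) -> np.ndarray:
    """Label samples 'high'/'low' at the fit's threshold; ties go to 'low'."""
    if not fit.converged:
        raise ValueError("cannot classify with an unconverged fit")
    values = np.asarray(values, dtype=float)
    return np.where(values > fit.classification_threshold, "high", "low")


def fit_expression_values(values, variant: str = "auto",
                          n_grid: int = 512, bandwidth: float | None = None
                          ) -> BimodalFit:
    """Convenience: KDE then mixture fit in one call.

    ``variant`` is 'auto' (residual-based selection), 'equal_variance' or
    'unequal_variance'.
    """
    curve = estimate_density(values, n_grid=n_grid, bandwidth=bandwidth)
    if variant == "auto":
        return select_variant(curve)
    return fit_bimodal(curve, variant)
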
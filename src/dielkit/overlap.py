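"""Circular activity densities and pairwise overlap coefficients.

Activity is a density on the sun-anchored circle. Each group's density
is estimated with a von Mises kernel whose concentration follows the
Ridout-Linkie optimal-smoothing rule, and temporal overlap between two
groups is the coefficient of overlap Delta ("Dhat") in [0, 1]:

* ``Dhat1`` integrates min(f, g) over a grid — preferred for small
  samples;
* ``Dhat4`` averages min(1, g/f) at the observed points of each sample —
  preferred for large samples (>= 75 events per group).

Uncertainty comes from a smoothed bootstrap (resampling from the fitted
kernel densities, 500 iterations by default) and a randomisation null
(both groups redrawn from the density fitted to the pooled sample) that
yields the probability the observed overlap arose by chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "CircularKDE",
    "OverlapResult",
    "vonmises_kappa_mle",
    "ridout_linkie_concentration",
    "fit_circular_kde",
    "dhat1",
    "dhat4",
    "overlap_estimate",
    "bootstrap_ci",
    "null_test",
    "compare_activity",
]

TWO_PI = 2.0 * np.pi
DEFAULT_GRID = 128
DHAT4_MIN_N = 75  # per-group sample size at which Dhat4 replaces Dhat1
_DENSITY_FLOOR = 1e-12
_EXACT_KERNEL_LIMIT = 4_000_000  # n*m above which Dhat4 interpolates from a fine grid


def _check_sample(x: np.ndarray, name: str = "sample") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"{name} must be 1-D with at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return np.remainder(x, TWO_PI)


def vonmises_kappa_mle(x: np.ndarray) -> float:
    """Maximum-likelihood von Mises concentration of a circular sample."""
    x = _check_sample(x)
    rbar = float(np.abs(np.mean(np.exp(1j * x))))
    if rbar < 1e-10:
        return 0.0
    if rbar > 1.0 - 1e-12:
        rbar = 1.0 - 1e-12

    def eq(k):
        return special.i1e(k) / special.i0e(k) - rbar

    k_max = 5e3
    if eq(k_max) < 0:  # resultant length beyond the solvable range: cap
        return float(k_max)
    return float(optimize.brentq(eq, 1e-8, k_max))


def ridout_linkie_concentration(x: np.ndarray) -> float:
    """Optimal von Mises kernel concentration for a circular sample.

    The plug-in rule treats the data as von Mises with MLE concentration
    kappa-hat and minimises asymptotic MISE:

        nu = ( 3 n kappa^2 I_2(2 kappa) / (4 sqrt(pi) I_0(kappa)^2) )^(2/5)
    """
    x = _check_sample(x)
    n = x.size
    kappa = max(vonmises_kappa_mle(x), 1e-6)
    # scaled Bessels keep the ratio finite for concentrated samples:
    # I2(2k)/I0(k)^2 = i2e(2k)*exp(2k) / (i0e(k)*exp(k))^2 = i2e(2k)/i0e(k)^2
    ratio = special.ive(2, 2 * kappa) / special.i0e(kappa) ** 2
    nu = (3.0 * n * kappa**2 * ratio / (4.0 * np.sqrt(np.pi))) ** 0.4
    return float(max(nu, 1e-3))


@dataclass
class CircularKDE:
    """Von Mises kernel density estimate on the sun-anchored circle."""

    data: np.ndarray
    kappa: float
    adjust: float
    grid: np.ndarray
    density: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = int(self.data.size)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Exact kernel density at arbitrary angles."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return _kernel_density(t, self.data, self.kappa)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Density at arbitrary angles by periodic linear interpolation of the grid."""
        t = np.remainder(np.asarray(t, dtype=float), TWO_PI)
        gx = np.append(self.grid, TWO_PI)
        gy = np.append(self.density, self.density[0])
        return np.interp(t, gx, gy)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Smoothed-bootstrap draw: data point plus von Mises kernel noise."""
        idx = rng.integers(0, self.n, size=size)
        return np.remainder(self.data[idx] + rng.vonmises(0.0, self.kappa, size=size), TWO_PI)


def _kernel_density(t: np.ndarray, data: np.ndarray, kappa: float) -> np.ndarray:
    # mean of von Mises kernels centred at the data; ive avoids overflow at large kappa
    delta = t[:, None] - data[None, :]
    log_norm = np.log(TWO_PI) + np.log(special.i0e(kappa)) + kappa
    return np.exp(kappa * np.cos(delta) - log_norm).mean(axis=1)


def fit_circular_kde(sample: np.ndarray, adjust: float = 1.0, n_grid: int = DEFAULT_GRID) -> CircularKDE:
    """Fit the von Mises KDE with Ridout-Linkie smoothing scaled by ``adjust``.

    The kernel concentration is the optimal rule divided by ``adjust``
    (larger ``adjust`` -> smoother estimate), matching the convention of
    the estimator literature this follows. Density values are returned
    on ``n_grid`` equally spaced points of [0, 2*pi).
    """
    x = _check_sample(sample)
    if adjust <= 0:
        raise ValueError("adjust must be positive")
    if np.ptp(x) < 1e-12:
        warnings.warn("all observations identical; density is near-degenerate")
    kappa = ridout_linkie_concentration(x) / adjust
    grid = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    dens = _kernel_density(grid, x, kappa)
    # renormalise on the circle (periodic rectangle rule == circular trapezoid)
    dens = dens / (dens.sum() * TWO_PI / n_grid)
    return CircularKDE(data=x, kappa=kappa, adjust=adjust, grid=grid, density=dens)


def circular_integral(grid: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal integral over the full circle of a periodic grid function."""
    step = TWO_PI / grid.size
    return float(values.sum() * step)


def dhat1(sample_a: np.ndarray, sample_b: np.ndarray, adjust: float = 0.8, n_grid: int = DEFAULT_GRID) -> float:
    """Overlap coefficient Dhat1 = integral of min(f, g) on a shared grid."""
    f = fit_circular_kde(sample_a, adjust=adjust, n_grid=n_grid)
    g = fit_circular_kde(sample_b, adjust=adjust, n_grid=n_grid)
    return float(np.clip(circular_integral(f.grid, np.minimum(f.density, g.density)), 0.0, 1.0))


def dhat4(sample_a: np.ndarray, sample_b: np.ndarray, adjust: float = 1.0) -> float:
    """Overlap coefficient Dhat4: mean of min(1, g/f) at A's points and min(1, f/g) at B's.

    For very large samples the densities are interpolated from a 512-point
    grid instead of the exact n x m kernel sum; the interpolation error is
    far below sampling noise at those sizes.
    """
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    f = fit_circular_kde(a, adjust=adjust, n_grid=512)
    g = fit_circular_kde(b, adjust=adjust, n_grid=512)
    exact = a.size * b.size <= _EXACT_KERNEL_LIMIT
    fa = f(a) if exact else f.interp(a)
    ga = g(a) if exact else g.interp(a)
    fb = f(b) if exact else f.interp(b)
    gb = g(b) if exact else g.interp(b)
    if np.any(fa < _DENSITY_FLOOR) or np.any(gb < _DENSITY_FLOOR):
        warnings.warn("near-zero density at sample points; flooring at 1e-12")
    fa = np.maximum(fa, _DENSITY_FLOOR)
    gb = np.maximum(gb, _DENSITY_FLOOR)
    val = 0.5 * (np.minimum(1.0, ga / fa).mean() + np.minimum(1.0, fb / gb).mean())
    return float(np.clip(val, 0.0, 1.0))


def _dispatch(n_a: int, n_b: int, dhat_type: str | None) -> str:
    if dhat_type is not None:
        if dhat_type not in ("Dhat1", "Dhat4"):
            raise ValueError("dhat_type must be 'Dhat1' or 'Dhat4'")
        return dhat_type
    return "Dhat1" if min(n_a, n_b) < DHAT4_MIN_N else "Dhat4"


def _estimate(sample_a, sample_b, dhat_type: str, adjust: float | None) -> float:
    if dhat_type == "Dhat1":
        return dhat1(sample_a, sample_b, adjust=0.8 if adjust is None else adjust)
    return dhat4(sample_a, sample_b, adjust=1.0 if adjust is None else adjust)


@dataclass
class OverlapResult:
    """Pairwise activity-overlap estimate with bootstrap CI and randomisation p."""

    dhat_type: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_a: int = 0
    n_b: int = 0
    n_boot: int = 0
    p_null: float | None = None
    seed: int | None = None


def overlap_estimate(sample_a, sample_b, dhat_type: str | None = None, adjust: float | None = None) -> OverlapResult:
    """Point estimate of activity overlap with sample-size-based dispatch.

    Dhat1 is used when the smaller group has fewer than 75 events, Dhat4
    otherwise; pass ``dhat_type`` to override. Groups below 25 events
    trigger a warning (too sparse for a reliable activity profile).
    """
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    if min(a.size, b.size) < 25:
        warnings.warn("fewer than 25 events in a group; overlap estimate will be imprecise")
    kind = _dispatch(a.size, b.size, dhat_type)
    est = _estimate(a, b, kind, adjust)
    return OverlapResult(dhat_type=kind, estimate=est, n_a=a.size, n_b=b.size)


def bootstrap_ci(
    sample_a,
    sample_b,
    n_boot: int = 500,
    seed: int | np.random.Generator | None = None,
    dhat_type: str | None = None,
    smoothed: bool = True,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bootstrap percentile CI for the overlap coefficient.

    By default each group is resampled from its fitted kernel density
    (smoothed bootstrap); ``smoothed=False`` resamples observations with
    replacement. The percentile interval is bias-corrected by shifting
    the bootstrap distribution so its mean matches the point estimate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    kind = _dispatch(a.size, b.size, dhat_type)
    est = _estimate(a, b, kind, None)
    fa = fit_circular_kde(a)
    fb = fit_circular_kde(b)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        if smoothed:
            ra = fa.sample(a.size, rng)
            rb = fb.sample(b.size, rng)
        else:
            ra = a[rng.integers(0, a.size, a.size)]
            rb = b[rng.integers(0, b.size, b.size)]
        reps[i] = _estimate(ra, rb, kind, None)
    shifted = reps - reps.mean() + est
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(shifted, [alpha, 1.0 - alpha])
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def null_test(
    sample_a,
    sample_b,
    n_reps: int = 500,
    seed: int | np.random.Generator | None = None,
    dhat_type: str | None = None,
) -> float:
    """Probability that an overlap this low arose by chance.

    Null replicates draw both groups, at their observed sizes, from the
    kernel density fitted to the pooled sample; pNull is the proportion
    of null overlaps <= the observed one (one-sided: small pNull means
    the groups overlap less than same-distribution sampling explains).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    kind = _dispatch(a.size, b.size, dhat_type)
    obs = _estimate(a, b, kind, None)
    pooled = fit_circular_kde(np.concatenate([a, b]))
    null = np.empty(n_reps)
    for i in range(n_reps):
        null[i] = _estimate(pooled.sample(a.size, rng), pooled.sample(b.size, rng), kind, None)
    return float(np.mean(null <= obs))


def compare_activity(
    sample_a,
    sample_b,
    n_boot: int = 500,
    seed: int | None = None,
    dhat_type: str | None = None,
) -> OverlapResult:
    """Full pairwise comparison: point estimate, 500-rep bootstrap CI and pNull."""
    rng = np.random.default_rng(seed)
    res = overlap_estimate(sample_a, sample_b, dhat_type=dhat_type)
    res.ci_low, res.ci_high = bootstrap_ci(sample_a, sample_b, n_boot=n_boot, seed=rng, dhat_type=res.dhat_type)
    res.p_null = null_test(sample_a, sample_b, n_reps=n_boot, seed=rng, dhat_type=res.dhat_type)
    res.n_boot = n_boot
    res.seed = seed
    return res


def true_vonmises_overlap(mu1: float, kappa1: float, mu2: float, kappa2: float) -> float:
    """Exact overlap of two von Mises densities by adaptive quadrature.

    Reference functional for validating the sample-based estimators:
    integral over the circle of min(f, g) for the true densities.
    """
    f = stats.vonmises(kappa1, loc=mu1)
    g = stats.vonmises(kappa2, loc=mu2)

    def integrand(t):
        return np.minimum(f.pdf(t), g.pdf(t))

    val, _ = integrate.quad(integrand, -np.pi, np.pi, limit=400)
    return float(val)
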
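"""Predator-prey temporal coupling via Poisson GLMMs on hourly counts.

For each (response group, predictor group) pair, the sun-anchored hourly
event counts of the response are regressed on those of the predictor
with a log link, Poisson errors, and a protected-area random intercept:

    log E[y_ah] = alpha + beta * x_ah + b_a,   b_a ~ N(0, sigma^2)

A significantly positive beta (95% Wald CI above 0) is read as
bottom-up coupling — the response tracks predator activity; a
significantly negative beta as top-down — the response avoids predator
activity; otherwise no direction is called. The pairwise suite runs all
feasible guild-size combinations against large and small carnivores,
restricted to protected areas where large carnivores were detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import events as _events

__all__ = ["CouplingResult", "fit_coupling", "run_pairwise_suite", "group_events", "GROUP_LABELS"]

_LOGSD_BOUNDS = (-7.0, 3.0)
_Z95 = stats.norm.ppf(0.975)

GROUP_LABELS = [
    f"{size}_{guild}"
    for guild in ("carnivore", "herbivore", "insectivore", "omnivore")
    for size in ("large", "small")
]


class FitError(RuntimeError):
    """Poisson GLMM failed to converge or data were degenerate."""


@dataclass
class CouplingResult:
    """Estimated coupling between one response group and one predictor group."""

    response_group: str
    predictor_group: str
    beta: float
    ci_low: float
    ci_high: float
    direction: str          # bottom_up | top_down | none
    alpha: float
    sigma: float
    loglik: float
    n_response: int
    n_predictor: int
    sites_used: int

    @staticmethod
    def call_direction(ci_low: float, ci_high: float) -> str:
        if ci_low > 0.0:
            return "bottom_up"
        if ci_high < 0.0:
            return "top_down"
        return "none"


class _PoissonLaplace:
    """Inner Newton over (alpha, beta, b_sites) for fixed sigma; Laplace marginal outside."""

    def __init__(self, y, x, site):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.site = np.asarray(site, dtype=int)
        self.q = int(self.site.max()) + 1
        self.n = self.y.size
        self.theta = np.zeros(2 + self.q)
        self.theta[0] = np.log(max(self.y.mean(), 0.1))

    def _eta(self, theta):
        return theta[0] + theta[1] * self.x + theta[2:][self.site]

    def penalised(self, theta, s2):
        eta = np.clip(self._eta(theta), -30, 30)
        mu = np.exp(eta)
        ll = float(np.sum(self.y * eta - mu))  # log y! constant dropped
        pen = 0.5 * float(theta[2:] @ theta[2:]) / s2
        return ll - pen, mu

    def newton(self, s2, max_iter=100):
        theta = self.theta.copy()
        f, mu = self.penalised(theta, s2)
        q = self.q
        for _ in range(max_iter):
            r = self.y - mu
            g = np.concatenate([
                [r.sum(), r @ self.x],
                np.bincount(self.site, r, minlength=q) - theta[2:] / s2,
            ])
            if np.max(np.abs(g)) < 1e-9:
                break
            H = np.zeros((2 + q, 2 + q))
            H[0, 0] = mu.sum()
            H[0, 1] = H[1, 0] = mu @ self.x
            H[1, 1] = mu @ self.x**2
            gs = np.bincount(self.site, mu, minlength=q)
            gx = np.bincount(self.site, mu * self.x, minlength=q)
            H[0, 2:] = H[2:, 0] = gs
            H[1, 2:] = H[2:, 1] = gx
            H[2:, 2:] = np.diag(gs + 1.0 / s2)
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(2 + q), g)
            except np.linalg.LinAlgError as e:
                raise FitError(f"singular Hessian: {e}") from e
            t = 1.0
            for _ls in range(30):
                cand = theta + t * step
                f_new, mu_new = self.penalised(cand, s2)
                if f_new >= f - 1e-12:
                    theta, f, mu = cand, f_new, mu_new
                    break
                t *= 0.5
            else:
                break
        r = self.y - mu
        g = np.concatenate([
            [r.sum(), r @ self.x],
            np.bincount(self.site, r, minlength=self.q) - theta[2:] / s2,
        ])
        self.theta = theta
        return theta, f, mu, bool(np.max(np.abs(g)) < 1e-6)

    def marginal(self, log_sd):
        s2 = float(np.exp(2.0 * log_sd))
        theta, f, mu, conv = self.newton(s2)
        h_bb = np.bincount(self.site, mu, minlength=self.q) + 1.0 / s2
        ll = f - 0.5 * np.sum(np.log(h_bb)) - 0.5 * self.q * np.log(s2)
        return ll, theta, mu, conv

    def full_hessian(self, theta, mu, s2):
        q = self.q
        H = np.zeros((2 + q, 2 + q))
        H[0, 0] = mu.sum()
        H[0, 1] = H[1, 0] = mu @ self.x
        H[1, 1] = mu @ self.x**2
        gs = np.bincount(self.site, mu, minlength=q)
        gx = np.bincount(self.site, mu * self.x, minlength=q)
        H[0, 2:] = H[2:, 0] = gs
        H[1, 2:] = H[2:, 1] = gx
        H[2:, 2:] = np.diag(gs + 1.0 / s2)
        return H


def fit_coupling(
    pairs: pd.DataFrame,
    response_col: str = "response_count",
    predictor_col: str = "predictor_count",
    site_col: str = "protected_area",
    response_group: str = "response",
    predictor_group: str = "predictor",
) -> CouplingResult:
    """Fit the Poisson random-intercept GLMM to one hourly-count pair table.

    ``pairs`` has one row per protected area x anchored hour with the
    response and predictor counts. With a single area the random
    intercept is dropped (fixed-effects Poisson fit) with a warning.
    Raises :class:`FitError` on degenerate data (all-zero response) or
    non-convergence, naming the pair.
    """
    y = pairs[response_col].to_numpy(dtype=float)
    x = pairs[predictor_col].to_numpy(dtype=float)
    if not np.any(y > 0):
        raise FitError(f"{response_group} ~ {predictor_group}: response counts all zero")
    sites = pd.Categorical(pairs[site_col])
    site_idx = sites.codes.astype(int)
    q = len(sites.categories)
    core = _PoissonLaplace(y, x, site_idx)

    single = q < 2
    if single:
        warnings.warn("single protected area: dropping the random intercept (fixed-effects fit)")
        log_sd_hat = _LOGSD_BOUNDS[0]
    else:
        res = optimize.minimize_scalar(
            lambda ls: -core.marginal(ls)[0],
            bounds=_LOGSD_BOUNDS,
            method="bounded",
            options={"xatol": 1e-6},
        )
        log_sd_hat = float(res.x)
    ll, theta, mu, conv = core.marginal(log_sd_hat)
    if not conv:
        raise FitError(f"{response_group} ~ {predictor_group}: GLMM did not converge")
    s2 = float(np.exp(2.0 * log_sd_hat))
    H = core.full_hessian(theta, mu, s2)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as e:
        raise FitError(f"{response_group} ~ {predictor_group}: information matrix singular") from e
    beta = float(theta[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    lo, hi = beta - _Z95 * se, beta + _Z95 * se
    return CouplingResult(
        response_group=response_group,
        predictor_group=predictor_group,
        beta=beta,
        ci_low=lo,
        ci_high=hi,
        direction=CouplingResult.call_direction(lo, hi),
        alpha=float(theta[0]),
        sigma=0.0 if single else float(np.exp(log_sd_hat)),
        loglik=float(ll),
        n_response=int(y.sum()),
        n_predictor=int(x.sum()),
        sites_used=q,
    )


def group_events(events: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Attach guild/size group labels ('large_carnivore', ...) to events.

    Species in the 'excluded' size class (>580 kg, negligible predation
    risk) receive no group and drop out of the coupling analysis.
    """
    tr = traits.set_index("species")
    joined = events.join(tr[["guild", "size_class"]], on="species")
    joined = joined[joined["size_class"].isin(["small", "large"])].copy()
    joined["group"] = joined["size_class"] + "_" + joined["guild"]
    return joined


def run_pairwise_suite(
    events: pd.DataFrame,
    traits: pd.DataFrame,
    predictor_groups: tuple[str, ...] = ("large_carnivore", "small_carnivore"),
    min_events: int = 25,
) -> pd.DataFrame:
    """Run the coupling GLMM for every feasible response x predictor pair.

    Restricted to protected areas where large carnivores were detected.
    Pairs where either group has fewer than ``min_events`` events in
    those areas, or where the fit fails, are reported with status
    'skipped'/'failed' rather than silently dropped. Returns a tidy
    table (one row per attempted pair).
    """
    grouped = group_events(events, traits)
    pred_areas = sorted(grouped.loc[grouped["group"] == "large_carnivore", "protected_area"].unique())
    if not pred_areas:
        raise FitError("no protected area with large-carnivore detections")
    sub = grouped[grouped["protected_area"].isin(pred_areas)]

    counts = {g: _events.hourly_counts(sub[sub["group"] == g], areas=pred_areas) for g in GROUP_LABELS}
    rows = []
    for pred in predictor_groups:
        for resp in GROUP_LABELS:
            if resp == pred:
                continue
            n_resp = int(counts[resp].to_numpy().sum())
            n_pred = int(counts[pred].to_numpy().sum())
            base = {"response_group": resp, "predictor_group": pred,
                    "n_response": n_resp, "n_predictor": n_pred, "sites_used": len(pred_areas)}
            if min(n_resp, n_pred) < min_events:
                rows.append({**base, "status": "skipped", "beta": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan, "direction": "not_tested"})
                continue
            pairs = pd.DataFrame({
                "protected_area": np.repeat(pred_areas, 24),
                "anchored_hour": np.tile(np.arange(24), len(pred_areas)),
                "response_count": counts[resp].to_numpy().ravel(),
                "predictor_count": counts[pred].to_numpy().ravel(),
            })
            try:
                r = fit_coupling(pairs, response_group=resp, predictor_group=pred)
                rows.append({**base, "status": "ok", "beta": r.beta, "ci_lo": r.ci_low,
                             "ci_hi": r.ci_high, "direction": r.direction})
            except FitError as e:
                warnings.warn(str(e))
                rows.append({**base, "status": "failed", "beta": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan, "direction": "not_tested"})
    return pd.DataFrame(rows)
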
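"""Multinomial mixed models for diel activity.

The response is the diel category of each independent event — day
(reference), night, or twilight — modelled with a multinomial logit
whose linear predictors are functions of trophic guild and log body
mass, plus a protected-area random intercept per non-reference category
(independent across categories, each with its own variance).

Estimation maximises the Laplace-approximated marginal likelihood: an
outer optimisation over the two random-intercept log-SDs wraps an inner
penalised Newton solve over fixed effects and area intercepts jointly,
with the Laplace log-determinant taken over the random-effect block.
Candidate models (intercept-only up to guild x mass interaction) are
compared by AIC; models within 2 AIC units of the best are considered
equally supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize

__all__ = [
    "DielModel",
    "ModelRanking",
    "FitError",
    "fit_diel_model",
    "candidate_set",
    "fit_candidates",
    "select_model",
    "predict_probabilities",
    "guild_night_slopes",
    "nocturnality_ratio",
    "CONVERGENCE_TOL",
]

CATEGORIES = ("day", "night", "twilight")  # day is the reference
CONVERGENCE_TOL = 1e-6
_INNER_TOL = 1e-9
_LOGSD_BOUNDS = (-6.0, 3.0)


class FitError(RuntimeError):
    """Model could not be fitted (degenerate data or non-convergence)."""


@dataclass
class DielModel:
    """Fitted multinomial logit with protected-area random intercepts."""

    formula: str
    coef: pd.DataFrame              # index (category, term); columns estimate, se
    vcov: np.ndarray                # covariance of stacked (beta_night, beta_twilight)
    sigma_night: float
    sigma_twilight: float
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    k_params: int
    design_info: object
    converged: bool
    stage: str = "ML"
    single_group_fallback: bool = False
    logmass_range: tuple[float, float] | None = None
    random_effects: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def terms(self) -> list[str]:
        return list(self.design_info.column_names)


def _multinomial_parts(eta_n, eta_t, y):
    """Log-likelihood and category probabilities given linear predictors."""
    m = np.maximum(0.0, np.maximum(eta_n, eta_t))
    den = np.exp(-m) + np.exp(eta_n - m) + np.exp(eta_t - m)
    log_den = m + np.log(den)
    eta_obs = np.where(y == 1, eta_n, np.where(y == 2, eta_t, 0.0))
    ll = float(np.sum(eta_obs - log_den))
    p_n = np.exp(eta_n - log_den)
    p_t = np.exp(eta_t - log_den)
    return ll, p_n, p_t


def _group_sum_mat(area, vals, q):
    """(q, k) sums of row blocks of ``vals`` per area index."""
    out = np.zeros((q, vals.shape[1]))
    np.add.at(out, area, vals)
    return out


class _LaplaceCore:
    """Inner penalised-Newton machinery shared across outer variance evaluations."""

    def __init__(self, X, y, area, q):
        self.X = X
        self.y = y
        self.area = area
        self.n, self.p = X.shape
        self.q = q
        self.y1 = (y == 1).astype(float)
        self.y2 = (y == 2).astype(float)
        self.theta = np.zeros(2 * self.p + 2 * q)
        self.dim = self.theta.size

    def _unpack(self, theta):
        p, q = self.p, self.q
        return theta[:p], theta[p:2 * p], theta[2 * p:2 * p + q], theta[2 * p + q:]

    def _eta(self, theta):
        bn_f, bt_f, bn_r, bt_r = self._unpack(theta)
        return self.X @ bn_f + bn_r[self.area], self.X @ bt_f + bt_r[self.area]

    def penalised(self, theta, s2n, s2t):
        eta_n, eta_t = self._eta(theta)
        ll, p_n, p_t = _multinomial_parts(eta_n, eta_t, self.y)
        _, _, bn_r, bt_r = self._unpack(theta)
        pen = 0.5 * (bn_r @ bn_r / s2n + bt_r @ bt_r / s2t)
        return ll - pen, p_n, p_t

    def grad_hess(self, theta, s2n, s2t, p_n, p_t):
        X, area, p, q = self.X, self.area, self.p, self.q
        _, _, bn_r, bt_r = self._unpack(theta)
        rn = self.y1 - p_n
        rt = self.y2 - p_t
        g = np.concatenate([
            X.T @ rn,
            X.T @ rt,
            np.bincount(area, rn, minlength=q) - bn_r / s2n,
            np.bincount(area, rt, minlength=q) - bt_r / s2t,
        ])
        w_nn = p_n * (1.0 - p_n)
        w_tt = p_t * (1.0 - p_t)
        w_nt = -p_n * p_t
        H = np.zeros((self.dim, self.dim))
        sl_bn = slice(0, p)
        sl_bt = slice(p, 2 * p)
        sl_un = slice(2 * p, 2 * p + q)
        sl_ut = slice(2 * p + q, 2 * p + 2 * q)
        Xw = X * w_nn[:, None]
        H[sl_bn, sl_bn] = Xw.T @ X
        H[sl_bt, sl_bt] = (X * w_tt[:, None]).T @ X
        H[sl_bn, sl_bt] = H[sl_bt, sl_bn] = (X * w_nt[:, None]).T @ X
        H[sl_un, sl_bn] = _group_sum_mat(area, X * w_nn[:, None], q)
        H[sl_ut, sl_bt] = _group_sum_mat(area, X * w_tt[:, None], q)
        H[sl_un, sl_bt] = _group_sum_mat(area, X * w_nt[:, None], q)
        H[sl_ut, sl_bn] = H[sl_un, sl_bt]
        H[sl_bn, sl_un] = H[sl_un, sl_bn].T
        H[sl_bt, sl_ut] = H[sl_ut, sl_bt].T
        H[sl_bt, sl_un] = H[sl_un, sl_bt].T
        H[sl_bn, sl_ut] = H[sl_ut, sl_bn].T
        H[sl_un, sl_un] = np.diag(np.bincount(area, w_nn, minlength=q) + 1.0 / s2n)
        H[sl_ut, sl_ut] = np.diag(np.bincount(area, w_tt, minlength=q) + 1.0 / s2t)
        H[sl_un, sl_ut] = H[sl_ut, sl_un] = np.diag(np.bincount(area, w_nt, minlength=q))
        return g, H

    def newton(self, s2n, s2t, max_iter=100):
        theta = self.theta.copy()
        f, p_n, p_t = self.penalised(theta, s2n, s2t)
        for _ in range(max_iter):
            g, H = self.grad_hess(theta, s2n, s2t, p_n, p_t)
            if np.max(np.abs(g)) < _INNER_TOL:
                break
            # small ridge keeps near-separated fits solvable
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(self.dim), g)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise FitError(f"singular Hessian in inner solve: {e}") from e
            t = 1.0
            for _ls in range(30):
                cand = theta + t * step
                f_new, p_n_new, p_t_new = self.penalised(cand, s2n, s2t)
                if f_new >= f - 1e-12:
                    theta, f, p_n, p_t = cand, f_new, p_n_new, p_t_new
                    break
                t *= 0.5
            else:
                break
        g, H = self.grad_hess(theta, s2n, s2t, p_n, p_t)
        self.theta = theta
        converged = bool(np.max(np.abs(g)) < CONVERGENCE_TOL)
        return theta, f, H, converged

    def marginal_loglik(self, log_sd):
        """Laplace-approximated marginal log-likelihood at (log sd_night, log sd_twilight)."""
        s2n = float(np.exp(2.0 * log_sd[0]))
        s2t = float(np.exp(2.0 * log_sd[1]))
        theta, f_pen, H, converged = self.newton(s2n, s2t)
        p, q = self.p, self.q
        H_bb = H[2 * p:, 2 * p:]
        sign, logdet_h = np.linalg.slogdet(H_bb)
        if sign <= 0:
            return -np.inf, theta, H, False
        logdet_d = q * (np.log(s2n) + np.log(s2t))
        return f_pen - 0.5 * logdet_h - 0.5 * logdet_d, theta, H, converged


def _validate(data, response_col, group_col):
    counts = data[response_col].value_counts()
    empty = [c for c in CATEGORIES if counts.get(c, 0) == 0]
    if len(empty) > 1:
        raise FitError(f"fewer than 2 diel categories present; empty: {empty}")
    if empty:
        raise FitError(f"empty diel category: {empty[0]}")
    if data[group_col].nunique() < 1:
        raise FitError("no protected areas in data")


def fit_diel_model(
    data: pd.DataFrame,
    formula: str = "logmass * C(guild)",
    group_col: str = "protected_area",
    response_col: str = "diel_category",
) -> DielModel:
    """Fit the diel multinomial logit with protected-area random intercepts.

    ``data`` is one row per independent event with the diel category, a
    ``logmass`` column (any fixed log base; slopes are on that scale),
    ``guild`` and the grouping column. ``formula`` is the right-hand
    side for the shared fixed-effects design of both non-reference
    categories. With a single protected area the model falls back to a
    fixed-effects multinomial fit (variances pinned at zero) and warns.
    """
    _validate(data, response_col, group_col)
    dm = patsy.dmatrix(formula, data)
    X = np.asarray(dm, dtype=float)
    design_info = dm.design_info
    cat_codes = pd.Categorical(data[response_col], categories=list(CATEGORIES))
    if cat_codes.isna().any():
        bad = sorted(set(data[response_col]) - set(CATEGORIES))
        raise FitError(f"unknown diel categories: {bad}")
    y = cat_codes.codes.astype(int)
    areas = pd.Categorical(data[group_col])
    area_idx = areas.codes.astype(int)
    q = len(areas.categories)

    core = _LaplaceCore(X, y, area_idx, q)
    single = q == 1
    if single:
        warnings.warn("single protected area: fitting fixed effects only (variances pinned at 0)")
        log_sd_hat = np.array([-9.0, -9.0])  # variance ~1e-8: Laplace term numerically vanishes
        ll, theta, H, converged = core.marginal_loglik(log_sd_hat)
    else:
        def negll(ls):
            val = core.marginal_loglik(ls)[0]
            return -val if np.isfinite(val) else 1e12

        res = optimize.minimize(
            negll,
            x0=np.array([-1.2, -1.2]),
            method="L-BFGS-B",
            bounds=[_LOGSD_BOUNDS, _LOGSD_BOUNDS],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        log_sd_hat = res.x
        ll, theta, H, converged = core.marginal_loglik(log_sd_hat)
    if not converged:
        raise FitError(
            "inner Newton failed to reach the convergence tolerance; "
            "data may be separated or a category degenerate"
        )

    p = core.p
    try:
        H_inv = np.linalg.inv(H + 1e-10 * np.eye(H.shape[0]))
    except np.linalg.LinAlgError as e:
        raise FitError(f"information matrix not invertible: {e}") from e
    vcov_beta = H_inv[: 2 * p, : 2 * p]
    se = np.sqrt(np.maximum(np.diag(vcov_beta), 0.0))
    terms = list(design_info.column_names)
    coef = pd.DataFrame(
        {
            "estimate": theta[: 2 * p],
            "se": se,
        },
        index=pd.MultiIndex.from_product([["night", "twilight"], terms], names=["category", "term"]),
    )
    k = 2 * p + (0 if single else 2)
    bn_r = theta[2 * p: 2 * p + q]
    bt_r = theta[2 * p + q:]
    re = pd.DataFrame(
        {"night": bn_r, "twilight": bt_r}, index=pd.Index(areas.categories, name=group_col)
    )
    lm_range = None
    if "logmass" in data.columns:
        lm_range = (float(data["logmass"].min()), float(data["logmass"].max()))
    return DielModel(
        formula=formula,
        coef=coef,
        vcov=vcov_beta,
        sigma_night=0.0 if single else float(np.exp(log_sd_hat[0])),
        sigma_twilight=0.0 if single else float(np.exp(log_sd_hat[1])),
        loglik=float(ll),
        aic=float(2 * k - 2 * ll),
        n_obs=core.n,
        n_groups=q,
        k_params=k,
        design_info=design_info,
        converged=converged,
        single_group_fallback=single,
        logmass_range=lm_range,
        random_effects=re,
    )


def candidate_set() -> dict[str, str]:
    """The nested candidate-model formulas, intercept-only up to the interaction.

    Every formula carries the protected-area random intercepts; the set
    reflects the hypothesis structure (activity ~ mass, guild, or their
    interaction).
    """
    return {
        "intercept_only": "1",
        "mass": "logmass",
        "guild": "C(guild)",
        "mass_plus_guild": "logmass + C(guild)",
        "mass_by_guild": "logmass * C(guild)",
    }


def fit_candidates(data: pd.DataFrame, formulas: dict[str, str] | None = None, **kwargs) -> dict[str, DielModel]:
    """Fit every candidate formula; non-converging candidates are dropped with a warning."""
    formulas = candidate_set() if formulas is None else formulas
    fits: dict[str, DielModel] = {}
    for name, rhs in formulas.items():
        try:
            fits[name] = fit_diel_model(data, formula=rhs, **kwargs)
        except FitError as e:
            warnings.warn(f"candidate {name!r} failed to fit: {e}")
    if len(fits) == 0:
        raise FitError("no candidate model could be fitted")
    return fits


@dataclass
class ModelRanking:
    """AIC ranking of candidate models; ΔAIC < 2 marks the supported set."""

    table: pd.DataFrame  # columns: name, formula, k, loglik, aic, delta_aic, supported

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["name"])

    @property
    def supported(self) -> list[str]:
        return list(self.table.loc[self.table["supported"], "name"])


def select_model(fits: dict[str, DielModel]) -> ModelRanking:
    """Rank fitted candidates by AIC (ties broken by parameter count, then name)."""
    if not fits:
        raise ValueError("no fitted models to rank")
    rows = [
        {"name": n, "formula": m.formula, "k": m.k_params, "loglik": m.loglik, "aic": m.aic}
        for n, m in fits.items()
    ]
    tab = pd.DataFrame(rows).sort_values(["aic", "k", "name"], kind="mergesort").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    tab["supported"] = tab["delta_aic"] < 2.0
    return ModelRanking(table=tab)


def _design_rows(model: DielModel, new_data: pd.DataFrame) -> np.ndarray:
    (X,) = patsy.build_design_matrices([model.design_info], new_data)
    return np.asarray(X)


def predict_probabilities(
    model: DielModel,
    new_data: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Diel-category probabilities with simulation-based confidence intervals.

    Predictions are at the random-effect mode 0 (a typical protected
    area). CIs come from ``n_draws`` draws of the fixed-effect vector
    from its asymptotic normal distribution, propagating each draw
    through the softmax and taking probability quantiles; this behaves
    better near 0/1 than the delta method. If the fit recorded the
    observed ``logmass`` range, an ``extrapolated`` flag marks rows
    outside it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = _design_rows(model, new_data)
    p = X.shape[1]
    beta = model.coef["estimate"].to_numpy()
    beta_n, beta_t = beta[:p], beta[p:]

    def softmax_probs(bn, bt):
        eta_n = X @ bn
        eta_t = X @ bt
        m = np.maximum(0.0, np.maximum(eta_n, eta_t))
        den = np.exp(-m) + np.exp(eta_n - m) + np.exp(eta_t - m)
        p_n = np.exp(eta_n - m) / den
        p_t = np.exp(eta_t - m) / den
        return 1.0 - p_n - p_t, p_n, p_t

    p_day, p_night, p_twi = softmax_probs(beta_n, beta_t)
    draws = rng.multivariate_normal(beta, model.vcov, size=n_draws)
    sims = np.empty((n_draws, X.shape[0], 3))
    for i, d in enumerate(draws):
        sims[i, :, 0], sims[i, :, 1], sims[i, :, 2] = softmax_probs(d[:p], d[p:])
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(sims, alpha, axis=0)
    hi = np.quantile(sims, 1.0 - alpha, axis=0)

    out = new_data.reset_index(drop=True).copy()
    for j, cat in enumerate(["day", "night", "twilight"]):
        out[f"p_{cat}"] = (p_day, p_night, p_twi)[j]
        out[f"p_{cat}_lo"] = lo[:, j]
        out[f"p_{cat}_hi"] = hi[:, j]
    if model.logmass_range is not None and "logmass" in out.columns:
        lmin, lmax = model.logmass_range
        out["extrapolated"] = (out["logmass"] < lmin) | (out["logmass"] > lmax)
    return out


def guild_night_slopes(model: DielModel, guilds: "list[str]") -> pd.DataFrame:
    """Per-guild slope of the night-vs-day logit in log body mass, with SEs.

    Combines the main ``logmass`` coefficient with the guild interaction
    contrast (when present) using the fitted covariance; slopes are on
    whatever log scale the ``logmass`` column used at fit time.
    """
    terms = model.terms
    p = len(terms)
    rows = []
    for g in guilds:
        c = np.zeros(2 * p)  # contrast on the night block only
        if "logmass" not in terms:
            raise ValueError("model has no logmass term")
        c[terms.index("logmass")] = 1.0
        inter = f"logmass:C(guild)[T.{g}]"
        if inter in terms:
            c[terms.index(inter)] = 1.0
        est = float(c @ model.coef["estimate"].to_numpy())
        se = float(np.sqrt(c @ model.vcov @ c))
        rows.append({"guild": g, "slope": est, "se": se})
    return pd.DataFrame(rows)


def nocturnality_ratio(p_night_a: float, p_night_b: float) -> float:
    """Ratio of two nocturnal-activity probabilities, reported to 1 decimal.

    E.g. (0.60, 0.13) -> 4.6: the first group is 4.6 times more likely
    to be active at night than the second.
    """
    for p in (p_night_a, p_night_b):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"probability outside (0, 1]: {p}")
    return round(p_night_a / p_night_b, 1)
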
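"""Bayesian Gaussian linear mixed models for shape and size.

Model, per response r (a PC score or log centroid size, z-scored):

    y_ir = alpha_r + x_i' beta_r + u_{g(i),r} + e_ir
    u_{g,r} ~ Normal(0, tau_r^2)        (population random intercepts)
    e_ir    ~ Normal(0, sigma_r^2)

with an improper flat prior on (alpha_r, beta_r) and half-Student-t(3)
priors (scale 2.5 on the standardized scale) on tau_r and sigma_r.
Multivariate responses are fitted jointly with independent residuals across
responses — each response keeps its own coefficients, random intercepts and
scales, while the pointwise log-likelihood sums over responses so that WAIC
compares whole multivariate models.

Sampling is by Gibbs: coefficients and group levels have conjugate Gaussian
full conditionals; the half-t scales use the inverse-gamma parameter
expansion (a half-t(nu, A) scale is an inverse-gamma scale mixture), so
every update is exact.  All updates are vectorized across responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

__all__ = [
    "ModelSpec",
    "ScalingRecord",
    "PosteriorDraws",
    "FitSummary",
    "standardize",
    "fit",
    "split_rhat",
    "rhat",
    "waic",
    "compare",
    "bayes_r2",
    "marginal_effect",
    "summarize",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ModelSpec:
    """Specification of one mixed model.

    ``responses`` may hold one name (size model) or several (the PC1..PCm
    multivariate shape model).  ``sigma_fixed`` pins the residual scale to a
    known value (no prior), which exposes the conjugate special case used to
    validate the sampler.
    """

    responses: list[str]
    fixed_effects: list[str]
    random_group: Optional[str] = "population"
    standardize: bool = True
    family: str = "gaussian"
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    seed: int = 0
    halft_df: float = 3.0
    halft_scale: float = 2.5
    sigma_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("at least one response is required")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.family != "gaussian":
            raise ValueError("only the Gaussian family is supported")


@dataclass
class ScalingRecord:
    """Per-column centring/scaling used for standardization (z-scores)."""

    mean: dict[str, float]
    sd: dict[str, float]
    observed_min: dict[str, float] = field(default_factory=dict)
    observed_max: dict[str, float] = field(default_factory=dict)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, mu in self.mean.items():
            if col in out.columns:
                out[col] = (out[col] - mu) / self.sd[col]
        return out

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, mu in self.mean.items():
            if col in out.columns:
                out[col] = out[col] * self.sd[col] + mu
        return out

    def z(self, col: str, value: float) -> float:
        return (value - self.mean[col]) / self.sd[col]


def standardize(
    data: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Z-score the given columns; zero-variance columns are an error."""
    out = data.copy()
    record = ScalingRecord(mean={}, sd={})
    for col in columns:
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in data")
        vals = data[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"column {col!r} contains missing values")
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance")
        record.mean[col] = mu
        record.sd[col] = sd
        record.observed_min[col] = float(vals.min())
        record.observed_max[col] = float(vals.max())
        out[col] = (vals - mu) / sd
    return out, record


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of all model parameters.

    Arrays are indexed ``[draw, response, ...]``; ``chain_index`` maps each
    retained draw to its chain.  The (standardized) design is kept so that
    fitted values can be reconstructed draw by draw.
    """

    fixed: np.ndarray  # S x R x p
    intercepts: np.ndarray  # S x R
    group_levels: Optional[np.ndarray]  # S x R x G
    group_scale: Optional[np.ndarray]  # S x R
    residual_scale: np.ndarray  # S x R
    pointwise_loglik: np.ndarray  # S x n
    chain_index: np.ndarray  # S
    response_names: list[str]
    predictor_names: list[str]
    group_labels: Optional[list[str]]
    X: np.ndarray  # n x p (standardized predictors)
    Y: np.ndarray  # n x R (standardized responses)
    group_codes: Optional[np.ndarray]  # n
    scaling: Optional[ScalingRecord]
    spec: ModelSpec

    @property
    def n_draws(self) -> int:
        return self.fixed.shape[0]

    @property
    def n_obs(self) -> int:
        return self.pointwise_loglik.shape[1]

    def fixed_draws(self, predictor: str, response: Optional[str] = None) -> np.ndarray:
        """Draws of one predictor's coefficient: S x R, or S for one response."""
        j = self.predictor_names.index(predictor)
        out = self.fixed[:, :, j]
        if response is not None:
            out = out[:, self.response_names.index(response)]
        return out

    def by_chain(self, values: np.ndarray) -> np.ndarray:
        """Reshape per-draw values (S, ...) to (chains, draws_per_chain, ...)."""
        chains = int(self.chain_index.max()) + 1
        per = self.n_draws // chains
        return values.reshape(chains, per, *values.shape[1:])


@dataclass
class FitSummary:
    """Posterior summary table plus model-level criteria."""

    table: pd.DataFrame  # parameter, response, mean, sd, lower, upper, rhat
    waic: float
    waic_se: float
    bayes_r2: float
    max_rhat: float
    converged: bool  # all split-Rhat < 1.1


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _inv_gamma(rng: np.random.Generator, shape: float, rate: np.ndarray) -> np.ndarray:
    return rate / rng.gamma(shape, 1.0, size=np.shape(rate))


def _gibbs_chain(
    rng: np.random.Generator,
    W: np.ndarray,
    Y: np.ndarray,
    codes: Optional[np.ndarray],
    n_groups: int,
    spec: ModelSpec,
) -> dict[str, np.ndarray]:
    n, p1 = W.shape
    R = Y.shape[1]
    nu, A = spec.halft_df, spec.halft_scale

    WtW = W.T @ W
    L = cholesky(WtW, lower=True)
    Li = solve_triangular(L, np.eye(p1), lower=True)
    Asolve = Li.T  # Asolve @ Asolve.T == inv(WtW)

    has_group = codes is not None and n_groups >= 2
    counts = None
    if has_group:
        counts = np.bincount(codes, minlength=n_groups).astype(float)

    # initial values
    B = np.linalg.lstsq(W, Y, rcond=None)[0]  # p1 x R
    resid = Y - W @ B
    sig2 = np.maximum(resid.var(axis=0, ddof=0), 1e-8)
    if spec.sigma_fixed is not None:
        sig2 = np.full(R, float(spec.sigma_fixed) ** 2)
    tau2 = np.full(R, 0.25)
    a_sig = np.ones(R)
    a_tau = np.ones(R)
    U = np.zeros((n_groups, R)) if has_group else None

    keep = spec.iterations - spec.burn_in
    out = {
        "fixed": np.empty((keep, R, p1 - 1)),
        "intercepts": np.empty((keep, R)),
        "residual_scale": np.empty((keep, R)),
        "pointwise_loglik": np.empty((keep, n)),
    }
    if has_group:
        out["group_levels"] = np.empty((keep, R, n_groups))
        out["group_scale"] = np.empty((keep, R))

    for it in range(spec.iterations):
        # --- coefficients (conjugate Gaussian, flat prior)
        r1 = Y - U[codes] if has_group else Y
        bhat = cho_solve((L, True), W.T @ r1)
        B = bhat + (Asolve @ rng.standard_normal((p1, R))) * np.sqrt(sig2)[None, :]

        resid = Y - W @ B
        if has_group:
            # --- group levels (conjugate Gaussian)
            S = np.zeros((n_groups, R))
            np.add.at(S, codes, resid)
            prec = counts[:, None] / sig2[None, :] + 1.0 / tau2[None, :]
            mean = (S / sig2[None, :]) / prec
            U = mean + rng.standard_normal((n_groups, R)) / np.sqrt(prec)
            err = resid - U[codes]
            # --- group scale (half-t via inverse-gamma mixture)
            ssu = np.sum(U**2, axis=0)
            tau2 = _inv_gamma(rng, 0.5 * (n_groups + nu), nu / a_tau + 0.5 * ssu)
            a_tau = _inv_gamma(rng, 0.5 * (nu + 1.0), nu / tau2 + 1.0 / A**2)
        else:
            err = resid

        # --- residual scale
        if spec.sigma_fixed is None:
            ssr = np.sum(err**2, axis=0)
            sig2 = _inv_gamma(rng, 0.5 * (n + nu), nu / a_sig + 0.5 * ssr)
            a_sig = _inv_gamma(rng, 0.5 * (nu + 1.0), nu / sig2 + 1.0 / A**2)

        if it >= spec.burn_in:
            j = it - spec.burn_in
            out["fixed"][j] = B[1:].T
            out["intercepts"][j] = B[0]
            out["residual_scale"][j] = np.sqrt(sig2)
            if has_group:
                out["group_levels"][j] = U.T
                out["group_scale"][j] = np.sqrt(tau2)
            ll = -0.5 * (_LOG2PI + np.log(sig2))[None, :] - err**2 / (
                2.0 * sig2[None, :]
            )
            out["pointwise_loglik"][j] = ll.sum(axis=1)
    return out


def fit(data: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Fit the mixed model by Gibbs sampling.

    ``data`` must contain all response and fixed-effect columns plus the
    random-group column (if any).  Standardization (if enabled) is applied
    here and recorded for back-transformation.
    """
    cols = list(spec.responses) + list(spec.fixed_effects)
    scaling: Optional[ScalingRecord] = None
    work = data
    if spec.standardize:
        work, scaling = standardize(data, cols)

    X = work[list(spec.fixed_effects)].to_numpy(dtype=float)
    Y = work[list(spec.responses)].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("design contains missing or non-finite values")
    n = X.shape[0]
    W = np.column_stack([np.ones(n), X])

    codes: Optional[np.ndarray] = None
    labels: Optional[list[str]] = None
    n_groups = 0
    if spec.random_group is not None:
        groups = work[spec.random_group].astype(str).to_numpy()
        labels = sorted(set(groups))
        if len(labels) < 2:
            raise ValueError("random grouping factor needs at least 2 levels")
        lookup = {g: i for i, g in enumerate(labels)}
        codes = np.array([lookup[g] for g in groups])
        n_groups = len(labels)

    ss = np.random.SeedSequence(spec.seed)
    chain_out = []
    for child in ss.spawn(spec.chains):
        rng = np.random.default_rng(child)
        chain_out.append(_gibbs_chain(rng, W, Y, codes, n_groups, spec))

    def cat(key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in chain_out], axis=0)

    keep = spec.iterations - spec.burn_in
    chain_index = np.repeat(np.arange(spec.chains), keep)
    has_group = codes is not None
    return PosteriorDraws(
        fixed=cat("fixed"),
        intercepts=cat("intercepts"),
        group_levels=cat("group_levels") if has_group else None,
        group_scale=cat("group_scale") if has_group else None,
        residual_scale=cat("residual_scale"),
        pointwise_loglik=cat("pointwise_loglik"),
        chain_index=chain_index,
        response_names=list(spec.responses),
        predictor_names=list(spec.fixed_effects),
        group_labels=labels,
        X=X,
        Y=Y,
        group_codes=codes,
        scaling=scaling,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# diagnostics and criteria
# ---------------------------------------------------------------------------


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  Each chain is split in half; the
    statistic compares between- and within-half variances.  Zero total
    variance returns 1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 1 or n < 4:
        raise ValueError("need at least one chain of >= 4 draws")
    half = n // 2
    splits = np.concatenate(
        [chains[:, :half], chains[:, half : 2 * half]], axis=0
    )  # 2m x half
    w = splits.var(axis=1, ddof=1).mean()
    b = half * splits.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def rhat(draws: PosteriorDraws, predictor: str, response: Optional[str] = None) -> float:
    """Split-Rhat of one fixed-effect coefficient (max over responses if
    ``response`` is None and the model is multivariate)."""
    vals = draws.fixed_draws(predictor, response)
    by_chain = draws.by_chain(vals)
    if by_chain.ndim == 2:
        return split_rhat(by_chain)
    return max(split_rhat(by_chain[:, :, r]) for r in range(by_chain.shape[2]))


def waic(draws: PosteriorDraws) -> tuple[float, float, pd.DataFrame]:
    """Widely applicable information criterion on the deviance scale.

    lppd_i = log mean_t exp(loglik_it); p_i = var_t(loglik_it);
    WAIC = -2 * sum_i (lppd_i - p_i); se = sqrt(n) * sd_i of the pointwise
    contributions -2*(lppd_i - p_i).
    """
    ll = draws.pointwise_loglik
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    S, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - math.log(S)
    p_i = ll.var(axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    pointwise = -2.0 * elpd_i
    total = float(pointwise.sum())
    se = float(np.sqrt(n) * pointwise.std(ddof=1))
    table = pd.DataFrame(
        {"lppd": lppd_i, "p_waic": p_i, "waic": pointwise}
    )
    return total, se, table


def compare(fits: Sequence[tuple[str, PosteriorDraws]]) -> pd.DataFrame:
    """WAIC comparison table against the best (smallest-WAIC) model.

    ``d_waic`` of the best model is left missing (blank on output); the
    standard error of each difference is paired over observations.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {label: d.n_obs for label, d in fits}
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"fits cover different observations: {n_obs}")
    rows = []
    pointwise = {}
    for label, d in fits:
        total, se, table = waic(d)
        pointwise[label] = table["waic"].to_numpy()
        rows.append({"model": label, "waic": total, "se": se})
    df = pd.DataFrame(rows)
    best = df.loc[df["waic"].idxmin(), "model"]
    n = len(next(iter(pointwise.values())))
    d_waic, d_se = [], []
    for row in df.itertuples():
        if row.model == best:
            d_waic.append(np.nan)
            d_se.append(np.nan)
        else:
            diff = pointwise[row.model] - pointwise[best]
            d_waic.append(float(diff.sum()))
            d_se.append(float(np.sqrt(n) * diff.std(ddof=1)))
    df["d_waic"] = d_waic
    df["d_se"] = d_se
    return df.sort_values("waic", ignore_index=True)


def _fitted_chunk(draws: PosteriorDraws, sl: slice) -> np.ndarray:
    """Fitted values mu for a slice of draws: (s, n, R)."""
    B = draws.fixed[sl]  # s x R x p
    a = draws.intercepts[sl]  # s x R
    mu = np.einsum("np,srp->snr", draws.X, B) + a[:, None, :]
    if draws.group_levels is not None:
        u = draws.group_levels[sl][:, :, draws.group_codes]  # s x R x n
        mu = mu + u.transpose(0, 2, 1)
    return mu


def bayes_r2(draws: PosteriorDraws) -> dict[str, float]:
    """Posterior Bayes R²: per draw, var(fitted) / (var(fitted) + sigma²),
    averaged over responses for multivariate fits."""
    S = draws.n_draws
    vals = np.empty(S)
    step = max(1, 200_000 // max(1, draws.n_obs * len(draws.response_names)))
    for start in range(0, S, step):
        sl = slice(start, min(S, start + step))
        mu = _fitted_chunk(draws, sl)  # s x n x R
        var_fit = mu.var(axis=1, ddof=0)  # s x R
        r2 = var_fit / (var_fit + draws.residual_scale[sl] ** 2)
        vals[sl] = r2.mean(axis=1)
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return {
        "mean": float(vals.mean()),
        "lower": float(lo),
        "upper": float(hi),
    }


def marginal_effect(
    draws: PosteriorDraws,
    focal: str,
    levels: Sequence[float],
    response: Optional[str] = None,
) -> pd.DataFrame:
    """Posterior fitted values at chosen levels of one predictor.

    Other predictors sit at their means (zero on the standardized scale) and
    random effects at zero.  Levels are given on the original coding and
    z-scored through the recorded scaling; levels outside the observed range
    are computed with a warning flag in the output.
    """
    if focal not in draws.predictor_names:
        raise KeyError(f"{focal!r} is not a fixed effect of this model")
    j = draws.predictor_names.index(focal)
    resp_idx = (
        range(len(draws.response_names))
        if response is None
        else [draws.response_names.index(response)]
    )
    rows = []
    for level in levels:
        z = level
        outside = False
        if draws.scaling is not None and focal in draws.scaling.mean:
            z = draws.scaling.z(focal, level)
            outside = not (
                draws.scaling.observed_min[focal]
                <= level
                <= draws.scaling.observed_max[focal]
            )
        for r in resp_idx:
            fitted = draws.intercepts[:, r] + draws.fixed[:, r, j] * z
            lo, hi = np.quantile(fitted, [0.025, 0.975])
            rows.append(
                {
                    "response": draws.response_names[r],
                    "level": level,
                    "mean": float(fitted.mean()),
                    "lower": float(lo),
                    "upper": float(hi),
                    "extrapolated": outside,
                }
            )
    return pd.DataFrame(rows)


def summarize(draws: PosteriorDraws) -> FitSummary:
    """Posterior means, sds, 95% credible intervals and split-Rhat for every
    fixed effect and scale, plus WAIC and Bayes R²."""
    rows = []
    max_rhat = 1.0

    def add(name: str, response: str, values: np.ndarray) -> None:
        nonlocal max_rhat
        r = split_rhat(draws.by_chain(values))
        max_rhat = max(max_rhat, r)
        lo, hi = np.quantile(values, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "response": response,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)),
                "lower": float(lo),
                "upper": float(hi),
                "rhat": r,
            }
        )

    for r, resp in enumerate(draws.response_names):
        add("intercept", resp, draws.intercepts[:, r])
        for j, pred in enumerate(draws.predictor_names):
            add(pred, resp, draws.fixed[:, r, j])
        add("sigma", resp, draws.residual_scale[:, r])
        if draws.group_scale is not None:
            add("tau", resp, draws.group_scale[:, r])

    total, se, _ = waic(draws)
    r2 = bayes_r2(draws)
    return FitSummary(
        table=pd.DataFrame(rows),
        waic=total,
        waic_se=se,
        bayes_r2=r2["mean"],
        max_rhat=float(max_rhat),
        converged=bool(max_rhat < 1.1),
    )
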
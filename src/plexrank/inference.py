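"""Attribute-association inference for consensus (or layer) rankings.

Reversed ranks are regressed on node attributes with a negative-binomial
(NB2, log link) model including a group effect.  The primary fitter uses a
group random intercept whose marginal likelihood is integrated by
Gauss-Hermite quadrature; if that fit fails to converge it falls back,
with a recorded diagnostic, to group fixed effects.  Candidate models are
selected by AICc (all models within 4 points of the best) and weighted by
Akaike weights.

Because network metrics violate independence assumptions, coefficient
significance comes from node-label permutations: attribute rows are shuffled
jointly within each group (the network, and hence the rankings, is left
untouched), the same model is refit per replicate, and two-tailed empirical
p-values are computed from the null coefficient distributions.  Replicate
refits use a fast fixed-dispersion IRLS engine with group fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special

from .core_io import AttributeTable

__all__ = [
    "ModelSpec",
    "FitResult",
    "PermutationResult",
    "FittingError",
    "DEFAULT_CATALOGUE",
    "build_model_frame",
    "fit_nb_model",
    "aicc",
    "aicc_candidate_set",
    "permute_attributes",
    "permutation_test",
]

#: candidate-set inclusion threshold on delta-AICc
AICC_DELTA = 4.0

#: published top-model formulas over the attribute vocabulary; keys group
#: them by the outcome ranking they were fitted to
DEFAULT_CATALOGUE: dict[str, list[str]] = {
    "consensus": [
        "rank * sex * dc + msc * sex + rearing",
        "rank * sex * dc + msc + rearing",
    ],
    "aggression": [
        "rank * sex * dc",
        "rank * age * dc + sex",
    ],
    "status": [
        "rank * age * sex + dc",
    ],
    "grooming": [
        "rank * msc + sex + rearing",
        "rank * msc + sex",
        "rank + msc + sex + rearing",
        "rank * sex + msc",
        "rank + msc",
    ],
}


class FittingError(RuntimeError):
    """Model fitting failed after all fallbacks."""


@dataclass(frozen=True)
class ModelSpec:
    """A model formula over the attribute vocabulary.

    ``formula`` is a right-hand side over the variables ``rank`` (dominance
    rank as fraction outranked), ``sex``, ``dc`` (transformed dominance
    certainty), ``age``, ``msc`` (matriline size category), ``rearing``.
    ``group_effect`` is ``random`` (intercept; the default), ``fixed`` or
    ``none``.
    """

    formula: str
    name: str = ""
    group_effect: str = "random"

    def __post_init__(self) -> None:
        if self.group_effect not in {"random", "fixed", "none"}:
            raise ValueError(f"unknown group_effect {self.group_effect!r}")


@dataclass
class FitResult:
    """A fitted negative-binomial model."""

    spec: ModelSpec
    params: dict[str, float]  # fixed-effect terms only
    se: dict[str, float]  # Wald standard errors (Fisher information)
    alpha: float  # NB2 dispersion
    sigma_group: float | None  # random-intercept SD (None if fixed/none)
    llf: float
    k_params: int
    n_obs: int
    aicc: float
    converged: bool
    method: str  # "random_intercept" | "fixed_effects" | "plain"
    diagnostics: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf


@dataclass
class PermutationResult:
    """Observed coefficients against their permutation-null distributions."""

    spec: ModelSpec
    observed: dict[str, float]
    null: dict[str, np.ndarray]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    p_value: dict[str, float]  # corrected two-tailed empirical p
    tail_significant: dict[str, bool]  # raw 2.5% / 97.5% rule at p = 0.05
    n_replicates: int
    n_failed: int

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "observed": self.observed[t],
                "null_mean": self.null_mean[t],
                "null_sd": self.null_sd[t],
                "p": self.p_value[t],
                "tail_significant": self.tail_significant[t],
                "flag_p10": self.p_value[t] <= 0.10,
            }
            for t in self.observed
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model frame / design matrices
# ---------------------------------------------------------------------------

_FRAME_RENAMES = {
    "dominance_rank": "rank",
    "matriline_size_category": "msc",
}


def build_model_frame(outcome: dict[str, int], table: AttributeTable) -> pd.DataFrame:
    """Join an outcome map onto the attribute table.

    Returns one row per node with columns ``y``, ``rank``, ``sex``, ``dc``,
    ``age``, ``msc``, ``rearing``, ``group``.  Categorical baselines are
    female / mother-reared / small matriline, matching how coefficients are
    reported.
    """
    df = table.df.copy()
    missing = [n for n in df["node"] if n not in outcome]
    if missing:
        raise ValueError(f"outcome missing for node(s): {missing[:5]}")
    df["y"] = df["node"].map(outcome).astype(int)
    df = df.rename(columns=_FRAME_RENAMES)
    df["sex"] = pd.Categorical(df["sex"], categories=["female", "male"])
    df["rearing"] = pd.Categorical(df["rearing"], categories=["mother", "nursery"])
    df["msc"] = pd.Categorical(df["msc"], categories=["1-5", "6-10", "11+"])
    return df[["node", "group", "y", "rank", "sex", "dc", "age", "msc", "rearing"]]


def _design(frame: pd.DataFrame, spec: ModelSpec):
    y, x = patsy.dmatrices(
        f"y ~ {spec.formula}", frame, return_type="dataframe"
    )
    return np.asarray(y).ravel(), np.asarray(x), list(x.columns)


# ---------------------------------------------------------------------------
# negative-binomial likelihood machinery
# ---------------------------------------------------------------------------


def _nb2_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Elementwise NB2 log-pmf with dispersion alpha (var = mu + alpha mu^2)."""
    r = 1.0 / alpha
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * (np.log(r) - np.log(r + mu))
        + y * (np.log(mu) - np.log(r + mu))
    )


def _fit_nb_irls(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool]:
    """NB2 GLM with known dispersion via iteratively reweighted least squares.

    Returns (beta, log-likelihood, converged).  This is the fast engine used
    for permutation replicates; with warm starts it converges in a handful of
    p x p solves.
    """
    n, p = x.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 0.1))
    else:
        beta = beta0.copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)  # Fisher weights for log link
        z = eta + (y - mu) / mu
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtw @ x, xtw @ z, rcond=None)[0]
        ll = float(_nb2_loglik(y, np.exp(np.clip(x @ beta_new, -30, 30)), alpha).sum())
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        if step < tol or abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return beta, ll_old, converged


def _wald_se(x: np.ndarray, beta: np.ndarray, alpha: float) -> np.ndarray:
    """Standard errors from the Fisher information of beta at fixed alpha."""
    mu = np.exp(np.clip(x @ beta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    info = (x.T * w) @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))


def _moment_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments dispersion estimate, floored away from zero."""
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    return max(num / den, 1e-4) if den > 0 else 0.5


def fit_nb_plain(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float | None = None,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, bool]:
    """NB2 MLE without group structure.

    When ``alpha`` is given it is held fixed (one IRLS pass); otherwise it is
    profiled by alternating IRLS for beta with a 1-D dispersion update.
    Returns (beta, alpha, llf, converged).
    """
    if alpha is not None:
        beta, ll, conv = _fit_nb_irls(x, y, alpha, beta0=beta0)
        return beta, alpha, ll, conv
    a = 0.5
    beta = beta0
    ll = -np.inf
    conv = False
    for _ in range(30):
        beta, ll, conv = _fit_nb_irls(x, y, a, beta0=beta)
        mu = np.exp(np.clip(x @ beta, -30, 30))

        def nll(log_a, mu=mu):
            return -float(_nb2_loglik(y, mu, np.exp(log_a)).sum())

        res = optimize.minimize_scalar(nll, bounds=(-9.0, 5.0), method="bounded")
        a_new = float(np.exp(res.x))
        if abs(np.log(a_new) - np.log(a)) < 1e-7:
            a = a_new
            break
        a = a_new
    ll = float(_nb2_loglik(y, np.exp(np.clip(x @ beta, -30, 30)), a).sum())
    return beta, a, ll, conv


def _gh_marginal_loglik(
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    gh_x: np.ndarray,
    gh_w: np.ndarray,
) -> float:
    """Negative marginal log-likelihood of the random-intercept NB model.

    theta = (beta..., log alpha, log sigma); the group intercept u_g ~
    N(0, sigma^2) is integrated out with Gauss-Hermite quadrature.
    """
    p = x.shape[1]
    beta = theta[:p]
    alpha = float(np.exp(np.clip(theta[p], -12, 6)))
    sigma = float(np.exp(np.clip(theta[p + 1], -12, 4)))
    eta = np.clip(x @ beta, -30.0, 30.0)
    total = 0.0
    log_w = np.log(gh_w / np.sqrt(np.pi))
    for g in range(n_groups):
        mask = group_idx == g
        eta_g = eta[mask]
        y_g = y[mask]
        # quadrature nodes: u = sqrt(2) * sigma * z
        contrib = np.empty(len(gh_x))
        for q, z in enumerate(gh_x):
            mu = np.exp(np.clip(eta_g + np.sqrt(2.0) * sigma * z, -30.0, 30.0))
            contrib[q] = _nb2_loglik(y_g, mu, alpha).sum() + log_w[q]
        total += float(special.logsumexp(contrib))
    return -total


def fit_nb_model(
    spec: ModelSpec,
    outcome: dict[str, int],
    table: AttributeTable,
    gh_points: int = 20,
) -> FitResult:
    """Fit the negative-binomial model named by ``spec``.

    ``group_effect='random'`` integrates a Gaussian group intercept by
    Gauss-Hermite quadrature; on failure (or with a single group) the fit
    falls back to group fixed effects, recorded in ``diagnostics``.
    """
    frame = build_model_frame(outcome, table)
    y, x, terms = _design(frame, spec)
    n, p = x.shape
    if n <= p + 1:
        raise FittingError(f"n={n} too small for {p} parameters")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise FittingError("outcome must be nonnegative integers")

    groups = frame["group"].astype(str).to_numpy()
    group_levels = sorted(set(groups))
    n_groups = len(group_levels)
    effect = spec.group_effect
    diagnostics: dict = {}
    if effect == "random" and n_groups < 2:
        diagnostics["note"] = "single group: random intercept degenerates to plain fit"
        effect = "none"

    if effect == "random":
        result = _fit_random_intercept(
            spec, x, y, terms, groups, group_levels, gh_points, diagnostics
        )
        if result is not None:
            return result
        diagnostics["fallback"] = "random-intercept fit failed; using group fixed effects"
        effect = "fixed"

    if effect == "fixed":
        x_fe, terms_fe = _append_group_dummies(x, terms, groups, group_levels)
        beta, alpha, llf, conv = fit_nb_plain(x_fe, y)
        if not conv:
            raise FittingError(f"fixed-effects NB fit did not converge for {spec}")
        k = x_fe.shape[1] + 1  # + dispersion
        params = dict(zip(terms_fe, beta))
        se = _wald_se(x_fe, beta, alpha)
        return FitResult(
            spec=spec,
            params={t: float(v) for t, v in params.items()},
            se={t: float(s) for t, s in zip(terms_fe, se)},
            alpha=float(alpha),
            sigma_group=None,
            llf=llf,
            k_params=k,
            n_obs=n,
            aicc=aicc(llf, k, n),
            converged=True,
            method="fixed_effects",
            diagnostics=diagnostics,
        )

    beta, alpha, llf, conv = fit_nb_plain(x, y)
    if not conv:
        raise FittingError(f"NB fit did not converge for {spec}")
    k = p + 1
    se = _wald_se(x, beta, alpha)
    return FitResult(
        spec=spec,
        params={t: float(v) for t, v in zip(terms, beta)},
        se={t: float(s) for t, s in zip(terms, se)},
        alpha=float(alpha),
        sigma_group=None,
        llf=llf,
        k_params=k,
        n_obs=n,
        aicc=aicc(llf, k, n),
        converged=True,
        method="plain",
        diagnostics=diagnostics,
    )


def _append_group_dummies(x, terms, groups, group_levels):
    dummies = [(groups == g).astype(float) for g in group_levels[1:]]
    if not dummies:
        return x, list(terms)
    x_fe = np.column_stack([x] + dummies)
    terms_fe = list(terms) + [f"group[{g}]" for g in group_levels[1:]]
    return x_fe, terms_fe


def _fit_random_intercept(
    spec, x, y, terms, groups, group_levels, gh_points, diagnostics
) -> FitResult | None:
    n, p = x.shape
    group_idx = np.searchsorted(group_levels, groups)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(gh_points)

    # deterministic start: plain NB fit, sigma from group residual spread
    beta0, alpha0, _, conv0 = fit_nb_plain(x, y)
    if not conv0:
        beta0 = np.zeros(p)
        beta0[0] = np.log(max(y.mean(), 0.1))
        alpha0 = 0.5
    theta0 = np.concatenate([beta0, [np.log(alpha0), np.log(0.3)]])

    try:
        res = optimize.minimize(
            _gh_marginal_loglik,
            theta0,
            args=(x, y, group_idx, len(group_levels), gh_x, gh_w),
            method="BFGS",
            options={"maxiter": 500, "gtol": 1e-6},
        )
    except (ValueError, FloatingPointError) as exc:  # pragma: no cover
        diagnostics["random_intercept_error"] = str(exc)
        return None
    if not np.all(np.isfinite(res.x)):
        diagnostics["random_intercept_error"] = "non-finite optimum"
        return None
    # BFGS may stop on precision loss at an acceptable optimum; accept any
    # finite solution whose gradient norm is small
    grad_ok = res.success or (
        hasattr(res, "jac") and np.all(np.isfinite(res.jac)) and np.abs(res.jac).max() < 5e-2
    )
    if not grad_ok:
        diagnostics["random_intercept_error"] = res.message
        return None
    theta = res.x
    llf = -float(res.fun)
    beta = theta[:p]
    alpha = float(np.exp(theta[p]))
    sigma = float(np.exp(theta[p + 1]))
    k = p + 2  # + dispersion + random-intercept SD
    diagnostics["optimizer_message"] = res.message
    hess_inv = np.asarray(res.hess_inv)
    se = np.sqrt(np.clip(np.diag(hess_inv)[:p], 0.0, np.inf))
    return FitResult(
        spec=spec,
        params={t: float(v) for t, v in zip(terms, beta)},
        se={t: float(s) for t, s in zip(terms, se)},
        alpha=alpha,
        sigma_group=sigma,
        llf=llf,
        k_params=k,
        n_obs=n,
        aicc=aicc(llf, k, n),
        converged=True,
        method="random_intercept",
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# AICc model selection
# ---------------------------------------------------------------------------


def aicc(llf: float, k: int, n: int) -> float:
    """AIC corrected for small samples: AIC + 2K(K+1)/(n - K - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, K={k}")
    return 2.0 * k - 2.0 * llf + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_candidate_set(
    fits: list[FitResult], delta_max: float = AICC_DELTA
) -> tuple[list[FitResult], dict[str, float]]:
    """Retain fits within ``delta_max`` AICc of the best; Akaike-weight them.

    Weights are ``exp(-delta/2)`` renormalized over the retained set.  All
    fits must share the same observations.
    """
    if not fits:
        raise ValueError("need at least one fit")
    ns = {f.n_obs for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits on differing n: {sorted(ns)}")
    best = min(f.aicc for f in fits)
    candidates = [f for f in fits if f.aicc - best <= delta_max]
    rel = np.array([np.exp(-(f.aicc - best) / 2.0) for f in candidates])
    rel /= rel.sum()
    names = [f.spec.name or f.spec.formula for f in candidates]
    return candidates, dict(zip(names, rel.astype(float)))


# ---------------------------------------------------------------------------
# node-label permutations
# ---------------------------------------------------------------------------

_SHUFFLED_COLUMNS = [
    "sex",
    "age",
    "dominance_rank",
    "dominance_certainty",
    "matriline_size",
    "rearing",
]


def permute_attributes(
    table: AttributeTable, seed: int | np.random.Generator
) -> AttributeTable:
    """Shuffle attribute row-tuples jointly across nodes within each group.

    The node-to-network mapping is untouched; only which attribute bundle a
    node carries changes.  Joint shuffling preserves inter-attribute
    dependence (e.g. the rank-certainty U-shape) under the null.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = table.df.copy().reset_index(drop=True)
    for group in sorted(df["group"].unique()):
        idx = df.index[df["group"] == group].to_numpy()
        perm = rng.permutation(len(idx))
        block = df.loc[idx, _SHUFFLED_COLUMNS].to_numpy()
        df.loc[idx, _SHUFFLED_COLUMNS] = block[perm]
    return table.with_rows(df)


def _empirical_p(null: np.ndarray, observed: float) -> tuple[float, bool]:
    """Corrected two-tailed empirical p plus the raw 2.5%/97.5% tail call."""
    r = len(null)
    n_ge = int(np.sum(null >= observed))
    n_le = int(np.sum(null <= observed))
    q_upper = (1 + n_ge) / (1 + r)
    q_lower = (1 + n_le) / (1 + r)
    p = min(1.0, 2.0 * min(q_upper, q_lower))
    frac_larger = n_ge / r
    tail = frac_larger < 0.025 or frac_larger > 0.975
    return p, tail


def permutation_test(
    spec: ModelSpec,
    outcome: dict[str, int],
    table: AttributeTable,
    replicates: int = 1000,
    seed: int = 0,
    observed_fit: FitResult | None = None,
) -> PermutationResult:
    """Node-label permutation null for every coefficient of ``spec``.

    The rankings (and hence the outcome) depend only on the network, which
    permutations leave untouched, so the outcome is computed once; each
    replicate re-pairs outcomes with permuted attribute rows and refits.
    Replicates run on a fast fixed-dispersion IRLS engine with group fixed
    effects (dispersion taken from the observed fit); per-replicate RNG
    streams are spawned from the root seed so any replicate is reproducible
    independently of execution order.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if observed_fit is None:
        observed_fit = fit_nb_model(spec, outcome, table)
    terms = list(observed_fit.params)

    frame = build_model_frame(outcome, table)
    y, x, design_terms = _design(frame, spec)
    groups = frame["group"].astype(str).to_numpy()
    group_levels = sorted(set(groups))
    alpha = observed_fit.alpha

    root = np.random.SeedSequence(seed)
    streams = root.spawn(replicates)

    # permuting attribute rows within group and rebuilding the design equals
    # permuting the design rows within group (each row is a function of one
    # node's attributes only), so the design is built once
    group_indices = [
        np.flatnonzero(groups == g) for g in group_levels
    ]
    x_base_fe, terms_fe = _append_group_dummies(x, design_terms, groups, group_levels)

    null_rows = []
    n_failed = 0
    warm: np.ndarray | None = None
    n_attr_cols = x.shape[1]
    for stream in streams:
        rng = np.random.default_rng(stream)
        x_fe = x_base_fe.copy()
        for idx in group_indices:
            perm = rng.permutation(len(idx))
            # only the attribute-derived columns move; group dummies stay put
            x_fe[idx, :n_attr_cols] = x_base_fe[idx[perm], :n_attr_cols]
        beta, _, conv = _fit_nb_irls(x_fe, y, alpha, beta0=warm)
        if not conv or not np.all(np.isfinite(beta)):
            n_failed += 1
            continue
        warm = beta
        null_rows.append(dict(zip(terms_fe, beta)))
    if n_failed > 0.10 * replicates:
        import warnings

        warnings.warn(
            f"{n_failed}/{replicates} permutation refits failed and were "
            "dropped from the null",
            stacklevel=2,
        )
    if not null_rows:
        raise FittingError("all permutation replicates failed to fit")

    null: dict[str, np.ndarray] = {}
    p_value: dict[str, float] = {}
    tail: dict[str, bool] = {}
    observed = {}
    for term in terms:
        if term not in null_rows[0]:
            continue  # group dummies absent from a random-intercept observed fit
        draws = np.array([row[term] for row in null_rows])
        obs = observed_fit.params[term]
        null[term] = draws
        observed[term] = obs
        p_value[term], tail[term] = _empirical_p(draws, obs)
    return PermutationResult(
        spec=spec,
        observed=observed,
        null=null,
        null_mean={t: float(v.mean()) for t, v in null.items()},
        null_sd={t: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for t, v in null.items()},
        p_value=p_value,
        tail_significant=tail,
        n_replicates=replicates,
        n_failed=n_failed,
    )
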
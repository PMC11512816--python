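"""Trial-level behavioral models of avoidance choices.

Covers the model-free stage of the analysis: anticipation filtering,
per-participant avoidance summaries, Bayesian hierarchical logistic
regression of trial-by-trial choices (avoid = 1) with weakly informative
priors — normal(0, 2.5) coefficients, exponential(2) random-effect SDs,
LKJ(2) random-effect correlations — WAIC model comparison, posterior
summaries with Savage-Dickey Bayes factors, classical tests (Wilcoxon
against chance, paired t), the heart-rate x subjective-value
value-integration model, and the simulate-refit power procedure.

No probabilistic-programming backend is assumed: posterior sampling uses an
adaptive blocked random-walk Metropolis-within-Gibbs sampler written here,
with convergence monitored through split-R-hat and effective sample size
(arviz).  Correlation matrices are parameterized by canonical partial
correlations, under which the LKJ prior factorizes into independent
shifted-Beta densities (the vine construction), so no Jacobian bookkeeping
beyond the tanh transform is needed.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorFit",
    "InferenceSummary",
    "filter_anticipations",
    "avoidance_summary",
    "fit_hierarchical_logistic",
    "compare_waic",
    "summarize_effect",
    "wilcoxon_vs_chance",
    "paired_ttest",
    "fit_value_integration_model",
    "power_simulation",
]


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------


def filter_anticipations(
    trials: pd.DataFrame, min_rt: float = 0.150
) -> tuple[pd.DataFrame, int, float, int]:
    """Drop anticipatory responses (rt < ``min_rt``) from threat trials.

    Returns ``(kept, n_removed, pct_removed, n_missing)`` where
    ``pct_removed`` is the percentage of all threat trials, rounded to two
    decimals, and ``n_missing`` counts trials without a response (dropped
    separately).  Idempotent: refiltering the kept table removes nothing.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    t = trials[trials["trial_type"] == "threat"] if "trial_type" in trials.columns else trials
    n_total = len(t)
    rt = t["rt_s"].to_numpy(float)
    missing = ~np.isfinite(rt)
    anticip = np.isfinite(rt) & (rt < min_rt)
    kept = t[~missing & ~anticip].copy()
    n_removed = int(anticip.sum())
    pct = round(100.0 * n_removed / n_total, 2)
    return kept, n_removed, pct, int(missing.sum())


def avoidance_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition avoidance proportion and median RT.

    Cells in which a participant has no responded trials come back with
    missing values and ``flagged`` set.
    """
    rows = []
    for (pid, cond), g in trials.groupby(["participant_id", "condition"]):
        responded = g[g["response"].isin(["avoid", "approach"])]
        if responded.empty:
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "p_avoid": np.nan,
                    "median_rt": np.nan,
                    "n_responded": 0,
                    "flagged": True,
                }
            )
            continue
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "p_avoid": float((responded["response"] == "avoid").mean()),
                "median_rt": float(responded["rt_s"].median()),
                "n_responded": len(responded),
                "flagged": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model specification and priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of a hierarchical logistic choice model.

    Terms are drawn from {"condition", "rt", "condition:rt", "class", "hr",
    "sv"} and products thereof written with ":".  Coding: condition
    treatment-coded (unpredictable = 0, predictable = 1); class
    treatment-coded (SR = 0, GD = 1); rt grand-mean centered over the
    included trials.  ``random_terms`` lists the within-participant terms
    (plus the implicit intercept) that get correlated participant-level
    slopes.
    """

    fixed_terms: tuple[str, ...] = ("condition", "rt", "condition:rt")
    random_terms: tuple[str, ...] = ("condition", "rt", "condition:rt")
    name: str = "model"

    def __post_init__(self) -> None:
        between = {"class", "sv"}
        for term in self.random_terms:
            if set(term.split(":")) & between and term not in self.fixed_terms:
                raise ValueError(f"random slope for between-participant term {term!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for the hierarchical logistic model."""

    coef_sd: float = 2.5  # normal(0, coef_sd) on every fixed coefficient
    sd_rate: float = 2.0  # exponential(sd_rate) on random-effect SDs
    lkj_eta: float = 2.0  # LKJ(eta) on the random-effect correlation matrix

    def __post_init__(self) -> None:
        if min(self.coef_sd, self.sd_rate, self.lkj_eta) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 10000
    n_warmup: int = 2000
    thin: int = 1
    seed: int | None = None
    max_pointwise_draws: int = 2000  # cap on stored pointwise log-likelihoods


def _base_column(term: str, df: pd.DataFrame, rt_center: float) -> np.ndarray:
    if term == "condition":
        return (df["condition"].to_numpy() == "predictable").astype(float)
    if term == "rt":
        return df["rt_s"].to_numpy(float) - rt_center
    if term == "class":
        return (df["latent_class"].to_numpy() == "GD").astype(float)
    if term == "hr":
        return df["hr_change_z"].to_numpy(float)
    if term == "sv":
        return df["sv"].to_numpy(float)
    raise ValueError(f"unknown model term {term!r}")


def build_design(
    spec: ModelSpec, trials: pd.DataFrame, rt_center: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str], float]:
    """Response vector, fixed/random design matrices and grouping index."""
    y = (trials["response"].to_numpy() == "avoid").astype(float)
    if rt_center is None:
        rt_center = float(trials["rt_s"].mean()) if len(trials) else 0.0

    def col(term: str) -> np.ndarray:
        parts = term.split(":")
        out = np.ones(len(trials))
        for p in parts:
            out = out * _base_column(p, trials, rt_center)
        return out

    fixed_names = ["intercept"] + list(spec.fixed_terms)
    X = np.column_stack([np.ones(len(trials))] + [col(t) for t in spec.fixed_terms]) if len(
        trials
    ) else np.zeros((0, len(fixed_names)))
    random_names = ["intercept"] + list(spec.random_terms)
    Z = np.column_stack([np.ones(len(trials))] + [col(t) for t in spec.random_terms]) if len(
        trials
    ) else np.zeros((0, len(random_names)))
    pids = trials["participant_id"].to_numpy() if len(trials) else np.array([])
    participants = list(pd.unique(pids))
    gidx = np.array([participants.index(p) for p in pids], dtype=int)
    return y, X, Z, gidx, fixed_names, random_names, rt_center


# ---------------------------------------------------------------------------
# The Metropolis-within-Gibbs sampler
# ---------------------------------------------------------------------------


def _cpc_alphas(q: int, eta: float) -> np.ndarray:
    """Beta shape for each canonical partial correlation (row-major i>j)."""
    alphas = []
    for i in range(1, q):
        for j in range(i):
            alphas.append(eta + (q - 2 - j) / 2.0)
    return np.asarray(alphas)


def _chol_from_cpc(z: np.ndarray, q: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial corrs."""
    L = np.zeros((q, q))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, q):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[k] * rem
            rem *= math.sqrt(max(1.0 - z[k] ** 2, 1e-12))
            k += 1
        L[i, i] = rem
    return L


def _logistic_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class PosteriorFit:
    """Posterior draws plus everything WAIC and diagnostics need."""

    spec: ModelSpec
    priors: PriorSpec
    config: MCMCConfig
    fixed_names: list[str]
    random_names: list[str]
    draws: dict  # name -> (n_chains, n_saved) array
    pointwise_loglik: np.ndarray  # (n_subset_draws, n_trials)
    data_fingerprint: str
    rt_center: float
    n_participants: int
    acceptance: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"no parameter {name!r}; have {sorted(self.draws)}")
        return self.draws[name].reshape(-1)

    def diagnostics(self) -> pd.DataFrame:
        import arviz as az

        rows = []
        for name, arr in self.draws.items():
            ds = az.convert_to_dataset(arr)
            rows.append(
                {
                    "parameter": name,
                    "rhat": float(np.asarray(az.rhat(ds)["x"])),
                    "ess_bulk": float(np.asarray(az.ess(ds)["x"])),
                }
            )
        return pd.DataFrame(rows)

    def check_convergence(self, rhat_max: float = 1.01, ess_min: float = 400.0) -> None:
        diag = self.diagnostics()
        bad = diag[(diag["rhat"] > rhat_max) | (diag["ess_bulk"] < ess_min)]
        if not bad.empty:
            raise RuntimeError(
                "MCMC did not converge for "
                + ", ".join(f"{r.parameter} (rhat={r.rhat:.3f})" for r in bad.itertuples())
            )

    def waic(self) -> tuple[float, float]:
        """(waic, p_waic) on the deviance scale from pointwise log-likelihood."""
        ll = self.pointwise_loglik
        if ll.size == 0:
            raise ValueError("fit carries no pointwise log-likelihood")
        lppd = float(np.sum(_logmeanexp(ll, axis=0)))
        p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
        return -2.0 * (lppd - p_waic), p_waic


def _logmeanexp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis) - math.log(a.shape[axis])


def _data_fingerprint(y: np.ndarray, X: np.ndarray, gidx: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(np.ascontiguousarray(gidx).tobytes())
    h.update(str(X.shape[0]).encode())
    return h.hexdigest()


def fit_hierarchical_logistic(
    spec: ModelSpec,
    priors: PriorSpec,
    trials: pd.DataFrame,
    mcmc_cfg: MCMCConfig | None = None,
    rt_center: float | None = None,
    check_convergence: bool = False,
) -> PosteriorFit:
    """Bayesian hierarchical logistic regression of avoidance choices.

    Logit link; correlated participant-level effects for the intercept and
    every random term, with exponential SD priors and an LKJ prior on the
    correlation matrix.  With a zero-length trial table the sampler draws
    from the prior (prior-predictive mode).
    """
    cfg = MCMCConfig() if mcmc_cfg is None else mcmc_cfg
    y, X, Z, gidx, fixed_names, random_names, rt_center = build_design(spec, trials, rt_center)
    n, p = X.shape
    q = Z.shape[1]
    n_part = int(gidx.max()) + 1 if n else 0
    if n and n_part < 2:
        raise ValueError("hierarchical model needs at least two participants")
    rng_master = np.random.default_rng(cfg.seed)

    n_cpc = q * (q - 1) // 2
    alphas = _cpc_alphas(q, priors.lkj_eta)

    if n == 0:
        # prior-predictive mode: exact draws from the prior
        n_save = (cfg.n_iter - cfg.n_warmup) // cfg.thin
        draws = {}
        for name in fixed_names:
            draws[f"b_{name}"] = rng_master.normal(
                0.0, priors.coef_sd, (cfg.n_chains, n_save)
            )
        for name in random_names:
            draws[f"sd_{name}"] = rng_master.exponential(
                1.0 / priors.sd_rate, (cfg.n_chains, n_save)
            )
        return PosteriorFit(
            spec=spec,
            priors=priors,
            config=cfg,
            fixed_names=fixed_names,
            random_names=random_names,
            draws=draws,
            pointwise_loglik=np.zeros((0, 0)),
            data_fingerprint=_data_fingerprint(y, X, gidx),
            rt_center=rt_center,
            n_participants=0,
        )

    # per-participant views
    slices = [np.flatnonzero(gidx == i) for i in range(n_part)]
    Xi = [X[s] for s in slices]
    Zi = [Z[s] for s in slices]
    yi = [y[s] for s in slices]

    n_save = (cfg.n_iter - cfg.n_warmup) // cfg.thin
    all_draws = {
        **{f"b_{nm}": np.empty((cfg.n_chains, n_save)) for nm in fixed_names},
        **{f"sd_{nm}": np.empty((cfg.n_chains, n_save)) for nm in random_names},
    }
    for i2 in range(1, q):
        for j2 in range(i2):
            all_draws[f"corr_{random_names[i2]}_{random_names[j2]}"] = np.empty(
                (cfg.n_chains, n_save)
            )
    ll_store: list[np.ndarray] = []
    ll_keep = max(1, (cfg.n_chains * n_save) // max(cfg.max_pointwise_draws, 1))
    acc_stats = {"beta": 0, "b": 0, "hyper": 0, "total": 0}

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(rng_master.integers(2**31))
        beta = rng.normal(0.0, 0.1, p)
        b = rng.normal(0.0, 0.1, (n_part, q))
        log_sd = np.full(q, math.log(0.3))
        u = np.zeros(n_cpc)

        def chol_cov() -> np.ndarray:
            z = np.tanh(u)
            Lr = _chol_from_cpc(z, q)
            return np.exp(log_sd)[:, None] * Lr

        def logprior_b(bmat: np.ndarray, L: np.ndarray) -> float:
            w = solve_triangular(L, bmat.T, lower=True)
            return float(
                -0.5 * np.sum(w**2) - bmat.shape[0] * np.sum(np.log(np.diag(L)))
            )

        def logprior_hyper(log_sd_v: np.ndarray, u_v: np.ndarray) -> float:
            sd = np.exp(log_sd_v)
            lp = float(np.sum(-priors.sd_rate * sd + log_sd_v))  # Exp prior + Jacobian
            if n_cpc:
                z = np.tanh(u_v)
                lp += float(np.sum(alphas * np.log(np.maximum(1.0 - z**2, 1e-12))))
            return lp

        L = chol_cov()
        xb = [Xi[i] @ beta for i in range(n_part)]
        zb = [Zi[i] @ b[i] for i in range(n_part)]
        ll_i = np.array([_logistic_loglik(yi[i], xb[i] + zb[i]) for i in range(n_part)])
        lp_b = logprior_b(b, L)
        lp_hyper = logprior_hyper(log_sd, u)

        s_beta, s_b = 0.1, 0.3
        s_sd = np.full(q, 0.4)
        s_resc = np.full(q, 0.4)
        s_u = np.full(n_cpc, 0.4)
        target = 0.3
        k_save = 0
        for it in range(cfg.n_iter):
            adapt = it < cfg.n_warmup
            # --- fixed effects block
            prop = beta + s_beta * rng.standard_normal(p)
            xb_new = [Xi[i] @ prop for i in range(n_part)]
            ll_new = np.array(
                [_logistic_loglik(yi[i], xb_new[i] + zb[i]) for i in range(n_part)]
            )
            dlp = (
                ll_new.sum()
                - ll_i.sum()
                - 0.5 * np.sum(prop**2) / priors.coef_sd**2
                + 0.5 * np.sum(beta**2) / priors.coef_sd**2
            )
            acc = math.log(rng.uniform()) < dlp
            if acc:
                beta, xb, ll_i = prop, xb_new, ll_new
                acc_stats["beta"] += 1
            if adapt:
                s_beta *= math.exp(0.05 * ((1.0 if acc else 0.0) - target))

            # --- participant effects, one block each
            for i in range(n_part):
                bprop = b[i] + s_b * rng.standard_normal(q)
                zb_new_i = Zi[i] @ bprop
                ll_new_i = _logistic_loglik(yi[i], xb[i] + zb_new_i)
                w_new = solve_triangular(L, bprop, lower=True)
                w_old = solve_triangular(L, b[i], lower=True)
                dlp = ll_new_i - ll_i[i] - 0.5 * (w_new @ w_new - w_old @ w_old)
                acc = math.log(rng.uniform()) < dlp
                if acc:
                    b[i] = bprop
                    zb[i] = zb_new_i
                    ll_i[i] = ll_new_i
                    acc_stats["b"] += 1
                if adapt:
                    s_b *= math.exp(0.05 / n_part * ((1.0 if acc else 0.0) - target))
            lp_b = logprior_b(b, L)

            # --- hyperparameters: coordinate-wise scalar updates mix far
            # better than whole-block proposals for variance parameters
            for j in range(q):
                prop_sd = log_sd.copy()
                prop_sd[j] += s_sd[j] * rng.standard_normal()
                L_new = np.exp(prop_sd)[:, None] * _chol_from_cpc(np.tanh(u), q)
                lp_b_new = logprior_b(b, L_new)
                dlp = (
                    lp_b_new
                    + logprior_hyper(prop_sd, u)
                    - lp_b
                    - logprior_hyper(log_sd, u)
                )
                acc = math.log(rng.uniform()) < dlp
                if acc:
                    log_sd, L, lp_b = prop_sd, L_new, lp_b_new
                    acc_stats["hyper"] += 1
                if adapt:
                    s_sd[j] *= math.exp(0.1 * ((1.0 if acc else 0.0) - 0.44))
            # joint rescale move along the (sd_j, b_:,j) funnel direction:
            # b and sd scale together, so the MVN prior term and the
            # transform Jacobian cancel and only the likelihood and the
            # sd prior (with its log-scale Jacobian) remain
            for j in range(q):
                eps = s_resc[j] * rng.standard_normal()
                scale = math.exp(eps)
                b_new = b.copy()
                b_new[:, j] *= scale
                prop_sd = log_sd.copy()
                prop_sd[j] += eps
                zb_new = [
                    zb[i] + (scale - 1.0) * b[i, j] * Zi[i][:, j] for i in range(n_part)
                ]
                ll_new = np.array(
                    [_logistic_loglik(yi[i], xb[i] + zb_new[i]) for i in range(n_part)]
                )
                dlp = (
                    ll_new.sum()
                    - ll_i.sum()
                    + logprior_hyper(prop_sd, u)
                    - logprior_hyper(log_sd, u)
                )
                acc = math.log(rng.uniform()) < dlp
                if acc:
                    b, zb, ll_i, log_sd = b_new, zb_new, ll_new, prop_sd
                    L = np.exp(log_sd)[:, None] * _chol_from_cpc(np.tanh(u), q)
                    lp_b = logprior_b(b, L)
                if adapt:
                    s_resc[j] *= math.exp(0.1 * ((1.0 if acc else 0.0) - 0.44))

            for j in range(n_cpc):
                prop_u = u.copy()
                prop_u[j] += s_u[j] * rng.standard_normal()
                L_new = np.exp(log_sd)[:, None] * _chol_from_cpc(np.tanh(prop_u), q)
                lp_b_new = logprior_b(b, L_new)
                dlp = (
                    lp_b_new
                    + logprior_hyper(log_sd, prop_u)
                    - lp_b
                    - logprior_hyper(log_sd, u)
                )
                acc = math.log(rng.uniform()) < dlp
                if acc:
                    u, L, lp_b = prop_u, L_new, lp_b_new
                if adapt:
                    s_u[j] *= math.exp(0.1 * ((1.0 if acc else 0.0) - 0.44))
            acc_stats["total"] += 1

            if it >= cfg.n_warmup and (it - cfg.n_warmup) % cfg.thin == 0:
                for j, nm in enumerate(fixed_names):
                    all_draws[f"b_{nm}"][chain, k_save] = beta[j]
                sd = np.exp(log_sd)
                for j, nm in enumerate(random_names):
                    all_draws[f"sd_{nm}"][chain, k_save] = sd[j]
                if n_cpc:
                    R = _chol_from_cpc(np.tanh(u), q)
                    R = R @ R.T
                    for i2 in range(1, q):
                        for j2 in range(i2):
                            all_draws[f"corr_{random_names[i2]}_{random_names[j2]}"][
                                chain, k_save
                            ] = R[i2, j2]
                if (chain * n_save + k_save) % ll_keep == 0:
                    eta = X @ beta + np.einsum("ij,ij->i", Z, b[gidx])
                    ll_store.append(y * eta - np.logaddexp(0.0, eta))
                k_save += 1

    fit = PosteriorFit(
        spec=spec,
        priors=priors,
        config=cfg,
        fixed_names=fixed_names,
        random_names=random_names,
        draws=all_draws,
        pointwise_loglik=np.asarray(ll_store),
        data_fingerprint=_data_fingerprint(y, X, gidx),
        rt_center=rt_center,
        n_participants=n_part,
        acceptance=acc_stats,
    )
    if check_convergence:
        fit.check_convergence()
    return fit


# ---------------------------------------------------------------------------
# Model comparison and posterior summaries
# ---------------------------------------------------------------------------


def compare_waic(fits: dict[str, PosteriorFit] | list[PosteriorFit]) -> pd.DataFrame:
    """Rank fits of the same data by WAIC (lowest = best)."""
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.spec.name, f) for f in fits]
    fingerprints = {f.data_fingerprint for _, f in items}
    if len(fingerprints) > 1:
        raise ValueError("fits were not computed on identical data rows")
    rows = []
    for name, f in items:
        w, p_w = f.waic()
        rows.append({"model": name, "waic": w, "p_waic": p_w})
    table = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    table["delta_waic"] = table["waic"] - table["waic"].iloc[0]
    return table


@dataclass(frozen=True)
class InferenceSummary:
    median: float
    cri_95: tuple[float, float]
    p_below_zero: float
    p_above_zero: float
    bayes_factor_10: float
    wide_interval_flag: bool = False


def summarize_effect(
    fit: PosteriorFit,
    parameter: str,
    null_value: float = 0.0,
    prior_sd: float | None = None,
) -> InferenceSummary:
    """95% CrI, tail probabilities and a Savage-Dickey Bayes factor.

    BF10 is the prior density at ``null_value`` divided by the posterior
    density there (kernel estimate over the draws), against the stated
    normal(0, coef_sd) coefficient prior.
    """
    draws = fit.stacked(parameter)
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
    p_below = float(np.mean(draws < null_value))
    p_above = float(np.mean(draws > null_value))
    prior_sd = fit.priors.coef_sd if prior_sd is None else prior_sd
    prior_dens = stats.norm.pdf(null_value, 0.0, prior_sd)
    wide = False
    if draws.size < 200:
        warnings.warn("too few draws for a stable density at the null", stacklevel=2)
        wide = True
    try:
        post_dens = float(stats.gaussian_kde(draws)(null_value)[0])
    except np.linalg.LinAlgError:
        post_dens = np.nan
        wide = True
    bf10 = float(prior_dens / post_dens) if post_dens and np.isfinite(post_dens) else math.inf
    return InferenceSummary(
        median=float(med),
        cri_95=(float(lo), float(hi)),
        p_below_zero=p_below,
        p_above_zero=p_above,
        bayes_factor_10=bf10,
        wide_interval_flag=wide,
    )


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------


def _cohens_d_ci(
    diffs: np.ndarray, n_boot: int = 10000, seed: int | None = None
) -> tuple[float, tuple[float, float]]:
    sd = diffs.std(ddof=1)
    d = float(diffs.mean() / sd) if sd > 0 else math.inf * np.sign(diffs.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        s = rng.choice(diffs, size=diffs.size, replace=True)
        ssd = s.std(ddof=1)
        boots[k] = s.mean() / ssd if ssd > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    if boots.size == 0:
        return d, (d, d)
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return d, (float(lo), float(hi))


def wilcoxon_vs_chance(
    p_avoid: np.ndarray | list[float],
    chance: float = 0.5,
    n_boot: int = 10000,
    seed: int | None = None,
) -> dict:
    """Two-sided Wilcoxon signed-rank test of avoidance rates against chance."""
    x = np.asarray(p_avoid, float)
    diffs = x - chance
    nonzero = diffs[diffs != 0]
    if nonzero.size < 2:
        if nonzero.size == 0:
            return {"V": 0.0, "p": 1.0, "cohens_d": 0.0, "ci_d": (0.0, 0.0), "degenerate": True}
        raise ValueError("need at least two non-tied observations")
    method = "exact" if nonzero.size <= 25 else "auto"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    # report the positive-rank sum V (the signed-rank statistic convention)
    ranks = stats.rankdata(np.abs(nonzero))
    v_stat = float(ranks[nonzero > 0].sum())
    d, ci = _cohens_d_ci(diffs, n_boot=n_boot, seed=seed)
    return {
        "V": v_stat,
        "p": float(res.pvalue),
        "cohens_d": d,
        "ci_d": ci,
        "degenerate": False,
    }


def paired_ttest(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    n_boot: int = 10000,
    seed: int | None = None,
) -> dict:
    """Two-sided paired t-test with normality and variance-homogeneity checks."""
    a = np.asarray(values_a, float)
    bvals = np.asarray(values_b, float)
    if a.shape != bvals.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    diffs = a - bvals
    sd = diffs.std(ddof=1)
    out: dict = {"df": a.size - 1, "degenerate": False}
    if sd == 0:
        if np.allclose(diffs, 0):
            out.update({"t": 0.0, "p": 1.0, "cohens_d": 0.0, "ci_d": (0.0, 0.0)})
        else:
            out.update(
                {
                    "t": math.inf * np.sign(diffs.mean()),
                    "p": 0.0,
                    "cohens_d": math.inf * np.sign(diffs.mean()),
                    "ci_d": (np.nan, np.nan),
                    "degenerate": True,
                }
            )
        out["shapiro_p"] = np.nan
        out["levene_p"] = np.nan
        return out
    t, p = stats.ttest_rel(a, bvals)
    d, ci = _cohens_d_ci(diffs, n_boot=n_boot, seed=seed)
    out.update({"t": float(t), "p": float(p), "cohens_d": d, "ci_d": ci})
    out["shapiro_p"] = float(stats.shapiro(diffs).pvalue)
    out["levene_p"] = float(stats.levene(a, bvals).pvalue)
    return out


# ---------------------------------------------------------------------------
# Value-integration model (condition x rt x heart-rate x subjective value)
# ---------------------------------------------------------------------------


def fit_value_integration_model(
    trials: pd.DataFrame,
    hr_change: pd.DataFrame,
    sv_table: pd.DataFrame,
    priors: PriorSpec | None = None,
    mcmc_cfg: MCMCConfig | None = None,
) -> tuple[PosteriorFit, int]:
    """Hierarchical logistic model with the full condition x rt x heart-rate
    x subjective-value interaction set.

    ``hr_change`` must carry (participant_id, trial, hr_change_z);
    ``sv_table`` carries (participant_id, dyad_id, sv).  Trials without a
    matching SV are dropped (count returned).  Random structure: correlated
    participant intercept and condition slope (a documented reduction of the
    maximal structure for this 16-term design).
    """
    priors = PriorSpec() if priors is None else priors
    t = trials.merge(hr_change, on=["participant_id", "trial"], how="inner")
    merged = t.merge(sv_table[["participant_id", "dyad_id", "sv"]],
                     on=["participant_id", "dyad_id"], how="left")
    n_dropped = int(merged["sv"].isna().sum())
    merged = merged[merged["sv"].notna()]
    if merged["sv"].nunique() <= 1:
        raise ValueError("subjective values are constant; sv terms unidentifiable")
    import itertools as it

    base = ["condition", "rt", "hr", "sv"]
    fixed = []
    for r in range(1, 5):
        for combo in it.combinations(base, r):
            fixed.append(":".join(combo))
    spec = ModelSpec(
        fixed_terms=tuple(fixed),
        random_terms=("condition",),
        name="value_integration",
    )
    fit = fit_hierarchical_logistic(spec, priors, merged, mcmc_cfg)
    return fit, n_dropped


# ---------------------------------------------------------------------------
# Simulate-refit power analysis
# ---------------------------------------------------------------------------


def _simulate_choice_dataset(
    params: dict, n_participants: int, rng: np.random.Generator, n_trials: int = 64
) -> pd.DataFrame:
    """Artificial participants from extracted fixed effects and random SDs."""
    fixed = params["fixed"]
    sds = params.get("random_sd", {})
    rows = []
    for i in range(n_participants):
        b0 = rng.normal(0.0, sds.get("intercept", 0.0))
        b1 = rng.normal(0.0, sds.get("condition", 0.0))
        cond = np.repeat([0.0, 1.0], n_trials // 2)
        eta = (
            fixed.get("intercept", 0.0)
            + b0
            + (fixed.get("condition", 0.0) + b1) * cond
        )
        yy = (rng.uniform(size=n_trials) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": f"s{i:03d}",
                    "condition": np.where(cond == 1.0, "predictable", "unpredictable"),
                    "avoid": yy,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def power_simulation(
    seed_params: dict | PosteriorFit,
    sample_sizes: list[int],
    n_sims: int = 1000,
    alpha: float = 0.05,
    target_term: str = "condition",
    seed: int | None = None,
    n_trials: int = 64,
) -> pd.DataFrame:
    """Simulate-refit power for the condition effect at each sample size.

    For every candidate n, ``n_sims`` artificial datasets are simulated from
    the seed parameters (fixed effects plus random-effect SDs) and refit with
    a frequentist population-averaged logistic model (GEE, exchangeable
    working correlation, participant clusters); power is the proportion of
    refits whose Wald test of the target term has p < alpha.  Refit failures
    are counted separately, never as non-significant.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if isinstance(seed_params, PosteriorFit):
        fit = seed_params
        seed_params = {
            "fixed": {
                nm: float(np.median(fit.stacked(f"b_{nm}")))
                for nm in fit.fixed_names
                if nm in ("intercept", "condition")
            },
            "random_sd": {
                nm: float(np.median(fit.stacked(f"sd_{nm}")))
                for nm in fit.random_names
                if nm in ("intercept", "condition")
            },
        }
    rng = np.random.default_rng(seed)
    rows = []
    for n_part in sample_sizes:
        hits = 0
        failures = 0
        for _ in range(n_sims):
            data = _simulate_choice_dataset(seed_params, n_part, rng, n_trials=n_trials)
            data["cond"] = (data["condition"] == "predictable").astype(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.gee(
                        "avoid ~ cond",
                        groups="participant_id",
                        data=data,
                        family=sm.families.Binomial(),
                        cov_struct=sm.cov_struct.Exchangeable(),
                    )
                    res = model.fit()
                pval = float(res.pvalues["cond" if target_term == "condition" else target_term])
            except Exception:
                failures += 1
                continue
            if np.isfinite(pval) and pval < alpha:
                hits += 1
        n_ok = n_sims - failures
        rows.append(
            {
                "n_participants": n_part,
                "power": hits / n_ok if n_ok else np.nan,
                "n_sims": n_sims,
                "n_failures": failures,
            }
        )
    return pd.DataFrame(rows)
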
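"""Finite mixture of logistic regressions with participants as mixture units.

Each latent class k carries one fixed-effects logistic regression of
trial-level avoidance on (intercept, condition, centered RT, condition x RT).
A participant's class likelihood is the product of their trial likelihoods,
so responsibilities live at the participant level; the M-step refits each
component by responsibility-weighted maximum likelihood (Newton/IRLS).
Component count is chosen stepwise over K = 1..5 by BIC, and participants
get hard labels by maximum responsibility.

Components are canonically ordered by descending avoidance intercept before
reporting, so the class with the higher overall avoidance rate (the
stimulus-response-like class) is reproducibly component 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb, logsumexp

from .behavior import ModelSpec, build_design

__all__ = [
    "MixtureFit",
    "em_fit",
    "select_K",
    "assign_classes",
    "adjusted_rand_index",
]

_DEFAULT_SPEC = ModelSpec(
    fixed_terms=("condition", "rt", "condition:rt"),
    random_terms=(),
    name="mixture_component",
)


def _weighted_logistic_newton(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Weighted logistic ML by Newton-Raphson with a tiny ridge for stability."""
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - mu)) - ridge * beta
        W = w * mu * (1.0 - mu)
        H = (X * W[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _trial_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = X @ beta
    return y * eta - np.logaddexp(0.0, eta)


@dataclass
class MixtureFit:
    K: int
    coefficients: np.ndarray  # (K, p), canonical component order
    mixing_proportions: np.ndarray  # (K,)
    responsibilities: np.ndarray  # (n_participants, K)
    participants: list
    coef_names: list[str]
    log_likelihood: float
    bic: float
    n_em_iterations: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    collapsed: bool = False


def _e_step(
    part_ll: np.ndarray, log_pi: np.ndarray
) -> tuple[np.ndarray, float]:
    """Responsibilities and total log-likelihood from per-participant
    per-component log-likelihoods ``part_ll`` (n x K)."""
    joint = part_ll + log_pi[None, :]
    norm = logsumexp(joint, axis=1)
    resp = np.exp(joint - norm[:, None])
    return resp, float(norm.sum())


def em_fit(
    trials: pd.DataFrame,
    K: int,
    spec: ModelSpec = _DEFAULT_SPEC,
    max_iter: int = 1000,
    n_restarts: int = 20,
    tol: float = 1e-6,
    rng: np.random.Generator | int | None = None,
    rt_center: float | None = None,
) -> MixtureFit:
    """EM fit of a K-component mixture; best of ``n_restarts`` random starts.

    Random starts draw participant responsibilities from a symmetric
    Dirichlet.  Convergence is declared when the relative log-likelihood
    change drops below ``tol``; the log-likelihood is non-decreasing across
    iterations.  A component whose mixing proportion collapses below
    1/(10 n_participants) triggers a restart; persistent collapse returns the
    fit with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y, X, _, gidx, coef_names, _, rt_center = build_design(spec, trials, rt_center)
    participants = list(pd.unique(trials["participant_id"]))
    n_part = len(participants)
    collapse_floor = 1.0 / (10.0 * n_part)
    # participant -> trial-row aggregation matrix
    agg = np.zeros((n_part, len(y)))
    agg[gidx, np.arange(len(y))] = 1.0

    best: MixtureFit | None = None
    any_collapse = False
    for restart in range(max(n_restarts, 1)):
        if K == 1:
            resp = np.ones((n_part, 1))
        else:
            resp = rng.dirichlet(np.ones(K), size=n_part)
        pi = resp.mean(axis=0)
        betas = np.zeros((K, X.shape[1]))
        ll_old = -np.inf
        path = []
        collapsed = False
        it_done = max_iter
        for it in range(max_iter):
            # M-step: weighted logistic per component (trial weights are the
            # participant's responsibility), mixing proportions
            for k in range(K):
                w = resp[gidx, k]
                betas[k] = _weighted_logistic_newton(X, y, w, beta0=betas[k])
            pi = resp.mean(axis=0)
            if K > 1 and pi.min() < collapse_floor:
                collapsed = True
                break
            # E-step
            part_ll = agg @ np.column_stack(
                [_trial_loglik(X, y, betas[k]) for k in range(K)]
            )
            resp, ll = _e_step(part_ll, np.log(np.maximum(pi, 1e-300)))
            path.append(ll)
            if ll_old > -np.inf and (ll - ll_old) < tol * abs(ll_old):
                it_done = it + 1
                ll_old = ll
                break
            ll_old = ll
        if collapsed:
            any_collapse = True
            continue
        n_coef = K * X.shape[1] + (K - 1)
        bic = -2.0 * ll_old + n_coef * math.log(n_part)
        cand = MixtureFit(
            K=K,
            coefficients=betas,
            mixing_proportions=pi,
            responsibilities=resp,
            participants=participants,
            coef_names=coef_names,
            log_likelihood=ll_old,
            bic=bic,
            n_em_iterations=it_done,
            loglik_path=np.asarray(path),
            converged=it_done < max_iter,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
        if K == 1:
            break  # deterministic: restarts are identical
    if best is None:
        warnings.warn(
            f"all restarts collapsed a component at K={K}; consider a smaller K",
            stacklevel=2,
        )
        return em_fit(
            trials, K - 1, spec=spec, max_iter=max_iter, n_restarts=n_restarts,
            tol=tol, rng=rng, rt_center=rt_center,
        )
    best.collapsed = any_collapse
    # canonical order: descending avoidance intercept (SR-like first)
    order = np.argsort(-best.coefficients[:, 0], kind="stable")
    best.coefficients = best.coefficients[order]
    best.mixing_proportions = best.mixing_proportions[order]
    best.responsibilities = best.responsibilities[:, order]
    return best


def select_K(
    trials: pd.DataFrame,
    K_range: range | list[int] = range(1, 6),
    spec: ModelSpec = _DEFAULT_SPEC,
    rng: np.random.Generator | int | None = None,
    **em_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, MixtureFit]]:
    """Stepwise component-count selection by BIC over ``K_range``.

    BIC = -2 logL + p log(N) with N the number of participants (the
    independent mixture units) and p = K * n_coefficients + (K - 1) mixing
    proportions.  Returns (best_K, BIC table, fits).
    """
    K_list = list(K_range)
    if not K_list:
        raise ValueError("K_range is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows, fits = [], {}
    for K in K_list:
        try:
            f = em_fit(trials, K, spec=spec, rng=rng, **em_kwargs)
        except Exception as exc:  # noqa: BLE001
            rows.append({"K": K, "bic": np.nan, "log_likelihood": np.nan, "error": str(exc)})
            continue
        fits[K] = f
        rows.append(
            {"K": K, "bic": f.bic, "log_likelihood": f.log_likelihood, "error": ""}
        )
    table = pd.DataFrame(rows)
    if table["bic"].notna().sum() == 0:
        raise RuntimeError("every component count failed to fit")
    best_K = int(table.loc[table["bic"].idxmin(), "K"])
    return best_K, table, fits


def assign_classes(fit: MixtureFit) -> pd.DataFrame:
    """Hard labels by maximum responsibility (ties to the lower component)."""
    labels = np.argmax(fit.responsibilities, axis=1)  # argmax takes first max
    max_resp = fit.responsibilities[np.arange(len(labels)), labels]
    sorted_resp = np.sort(fit.responsibilities, axis=1)
    tie = fit.K > 1 and np.isclose(sorted_resp[:, -1], sorted_resp[:, -2]).any()
    out = pd.DataFrame(
        {
            "participant_id": fit.participants,
            "component": labels + 1,
            "max_responsibility": max_resp,
            "tie": [
                fit.K > 1 and bool(np.isclose(r[-1], r[-2]))
                for r in np.sort(fit.responsibilities, axis=1)
            ],
        }
    )
    if tie:
        warnings.warn("responsibility tie broken toward the lower component", stacklevel=2)
    return out


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (pair-counting form)."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    if a.size != b.size:
        raise ValueError("labelings differ in length")
    ct = pd.crosstab(a, b).to_numpy()
    n = a.size
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))
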
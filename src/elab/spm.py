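"""One-dimensional statistical parametric mapping of physiological epochs.

Per participant, each time point of the z-scored epochs is regressed on
effect-coded trial factors (condition, threat, outcome, response, all
coded -0.5/+0.5, interactions as products) plus a single non-time-varying
grand-mean-centered RT regressor.  Group inference per regressor runs a
one-sample t-test against zero across participants at every time point,
forms candidate clusters as supra-threshold runs of one sign longer than a
minimum duration (100 ms for heart-rate series, 20 ms for EMG), and
corrects their summed t-values (t_mass) by permutation: in each of the
permutations the beta series of a uniformly-drawn random number of
participants is replaced by zeros (no effect), and the maximum |t_mass|
within the observed cluster windows forms the null distribution.  A
participant-level sign-flip scheme is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "design_row_codes",
    "BetaSeries",
    "ClusterResult",
    "fit_trialwise_glm",
    "find_clusters",
    "permutation_test",
    "extract_ihr_change",
    "FORMULAS",
]

#: Regressor sets of the three trial-level formulas: formula 1 tests Threat
#: on all trials, formula 2 Outcome and formula 3 Response on threat trials
#: only (neutral trials have no approach/avoid semantics).
FORMULAS = {
    1: ("condition", "threat", "condition:threat"),
    2: ("condition", "outcome", "condition:outcome"),
    3: ("condition", "response", "condition:response"),
}

_CODES = {
    "condition": {"unpredictable": -0.5, "predictable": 0.5},
    "threat": {"neutral": -0.5, "threat": 0.5},
    "outcome": {"threat": -0.5, "safe": 0.5},
    "response": {"approach": -0.5, "avoid": 0.5},
}
_SOURCE_COLUMN = {
    "condition": "condition",
    "threat": "trial_type",
    "outcome": "outcome",
    "response": "response",
}


def design_row_codes(trials: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Effect-coded design columns (+/-0.5; interactions as products)."""
    cols = []
    for term in terms:
        col = np.ones(len(trials))
        for part in term.split(":"):
            mapping = _CODES[part]
            src = trials[_SOURCE_COLUMN[part]]
            col = col * src.map(mapping).to_numpy(float)
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(trials), 0))


@dataclass
class BetaSeries:
    """Per-participant, per-regressor time series of GLM coefficients."""

    betas: np.ndarray  # (n_participants, n_regressors, n_timepoints)
    regressors: list[str]
    time_axis: np.ndarray
    formula: int
    participants: list = field(default_factory=list)

    def for_regressor(self, name: str) -> np.ndarray:
        return self.betas[:, self.regressors.index(name), :]


def fit_trialwise_glm(
    epochs_by_participant: dict,
    trials_by_participant: dict,
    formula: int,
) -> BetaSeries:
    """Per-time-point OLS of z-scored epochs on the formula's regressors.

    ``epochs_by_participant`` maps participant -> EpochMatrix (z-scored),
    ``trials_by_participant`` maps participant -> trial table aligned with
    the epoch rows.  The RT regressor is a single per-trial scalar (grand-
    mean-centered over the pooled trials).  A participant whose design is
    rank-deficient (e.g. no approach responses) gets missing betas for the
    affected regressors.
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {sorted(FORMULAS)}")
    terms = FORMULAS[formula]
    participants = list(epochs_by_participant)
    rt_all = np.concatenate(
        [trials_by_participant[p]["rt_s"].to_numpy(float) for p in participants]
    )
    rt_center = float(np.nanmean(rt_all))

    regressors = ["intercept", *terms, "rt"]
    time_axis = epochs_by_participant[participants[0]].time_axis
    T = time_axis.size
    betas = np.full((len(participants), len(regressors), T), np.nan)
    for pi, p in enumerate(participants):
        ep = epochs_by_participant[p]
        tr = trials_by_participant[p]
        if len(tr) != ep.values.shape[0]:
            raise ValueError(f"epoch/trial row mismatch for participant {p}")
        codes = design_row_codes(tr, terms)
        rt = tr["rt_s"].to_numpy(float) - rt_center
        X = np.column_stack([np.ones(len(tr)), codes, rt])
        # identify estimable columns: drop constant-coded factors
        keep = np.array([np.ptp(X[:, j]) > 0 or j == 0 for j in range(X.shape[1])])
        Xk = X[:, keep]
        if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
            ind = np.linalg.qr(Xk, mode="r")
            diag = np.abs(np.diag(ind))
            keep_idx = np.flatnonzero(keep)
            keep[keep_idx[diag < 1e-10]] = False
            Xk = X[:, keep]
        coef, *_ = np.linalg.lstsq(Xk, ep.values, rcond=None)
        betas[pi, np.flatnonzero(keep), :] = coef
    return BetaSeries(
        betas=betas,
        regressors=regressors,
        time_axis=time_axis,
        formula=formula,
        participants=participants,
    )


@dataclass
class ClusterResult:
    regressor: str
    sign: int
    start_time: float
    end_time: float
    start_idx: int
    end_idx: int  # inclusive
    t_mass: float
    p_corr: float = np.nan


def _group_tseries(b: np.ndarray) -> tuple[np.ndarray, int]:
    """One-sample t against zero across participants (rows), nan-aware."""
    valid = np.isfinite(b).all(axis=1)
    bb = b[valid]
    n = bb.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants with non-missing betas")
    mean = bb.mean(axis=0)
    sd = bb.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t, n


def find_clusters(
    betas: BetaSeries,
    regressor: str,
    p_thres: float = 0.05,
    min_duration: float = 0.100,
) -> list[ClusterResult]:
    """Candidate clusters: same-sign supra-threshold t-runs longer than
    ``min_duration`` seconds (strictly longer, per the duration rule)."""
    b = betas.for_regressor(regressor)
    t, n = _group_tseries(b)
    crit = stats.t.ppf(1.0 - p_thres / 2.0, df=n - 1)
    dt = float(np.median(np.diff(betas.time_axis)))
    sign = np.where(t > crit, 1, np.where(t < -crit, -1, 0))
    clusters: list[ClusterResult] = []
    i = 0
    T = t.size
    while i < T:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < T and sign[j + 1] == sign[i]:
            j += 1
        # duration counts each point as one sampling period; the rule is
        # strictly "more than" the minimum
        n_pts = j - i + 1
        if n_pts * dt > min_duration + 1e-12:
            clusters.append(
                ClusterResult(
                    regressor=regressor,
                    sign=int(sign[i]),
                    start_time=float(betas.time_axis[i]),
                    end_time=float(betas.time_axis[j]),
                    start_idx=i,
                    end_idx=j,
                    t_mass=float(t[i : j + 1].sum()),
                )
            )
        i = j + 1
    return clusters


def _perm_tseries(
    bb: np.ndarray, n_perm: int, rng: np.random.Generator, scheme: str
) -> np.ndarray:
    """(n_perm, T) group t-series under the permutation scheme.

    scheme "zero-subset": the beta series of a uniformly drawn number of
    participants (1..n) is replaced by zeros.  scheme "sign-flip": each
    participant's series is multiplied by a random +/-1.
    """
    n, T = bb.shape
    if scheme == "zero-subset":
        masks = np.ones((n_perm, n))
        sizes = rng.integers(1, n + 1, size=n_perm)
        for k in range(n_perm):
            masks[k, rng.choice(n, size=sizes[k], replace=False)] = 0.0
        S1 = masks @ bb
        S2 = masks @ (bb**2)
    elif scheme == "sign-flip":
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
        S1 = flips @ bb
        S2 = np.broadcast_to((bb**2).sum(axis=0), (n_perm, T))
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    mean = S1 / n
    var = (S2 - S1**2 / n) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tperm = mean / np.sqrt(var / n)
    return np.nan_to_num(tperm)


def _max_run_tmass(
    trow: np.ndarray, crit: float, min_pts_excl: float, dt: float
) -> float:
    """Largest |sum of t| over supra-threshold same-sign runs longer than
    the duration rule, for one permuted t-series."""
    sign = np.where(trow > crit, 1, np.where(trow < -crit, -1, 0))
    best = 0.0
    i, T = 0, trow.size
    while i < T:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < T and sign[j + 1] == sign[i]:
            j += 1
        if (j - i + 1) * dt > min_pts_excl + 1e-12:
            best = max(best, abs(trow[i : j + 1].sum()))
        i = j + 1
    return best


def permutation_test(
    betas: BetaSeries,
    clusters: list[ClusterResult],
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    scheme: str = "zero-subset",
    null_statistic: str | None = None,
    p_thres: float = 0.05,
    min_duration: float = 0.100,
) -> list[ClusterResult]:
    """Cluster-corrected p-values against the permutation null.

    With the default "zero-subset" scheme the null statistic is the max
    |t_mass| within the observed cluster windows (windows fixed, matching a
    per-detected-cluster null).  With the "sign-flip" scheme — or when
    ``null_statistic="max-over-time"`` — clusters are re-detected in every
    permuted series and the max cluster |t_mass| over the whole series forms
    the null, the conventional family-wise-valid construction (the fixed-
    window null is badly anticonservative under sign flips because flipping
    destroys the very effect that selected the windows).  p_corr is floored
    at 1/n_perm; significance at p_corr < 0.05.
    """
    if not clusters:
        return []
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is too small for stable p-values", stacklevel=2)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if null_statistic is None:
        null_statistic = "windows" if scheme == "zero-subset" else "max-over-time"
    b = betas.for_regressor(clusters[0].regressor)
    valid = np.isfinite(b).all(axis=1)
    bb = b[valid]
    tperm = _perm_tseries(bb, n_perm, rng, scheme)
    if null_statistic == "windows":
        null = np.zeros(n_perm)
        for c in clusters:
            null = np.maximum(
                null, np.abs(tperm[:, c.start_idx : c.end_idx + 1].sum(axis=1))
            )
    else:
        crit = stats.t.ppf(1.0 - p_thres / 2.0, df=bb.shape[0] - 1)
        dt = float(np.median(np.diff(betas.time_axis)))
        null = np.array(
            [_max_run_tmass(tperm[k], crit, min_duration, dt) for k in range(n_perm)]
        )
    out = []
    for c in clusters:
        p = float(np.mean(null >= abs(c.t_mass)))
        p = max(p, 1.0 / n_perm)
        out.append(
            ClusterResult(
                regressor=c.regressor,
                sign=c.sign,
                start_time=c.start_time,
                end_time=c.end_time,
                start_idx=c.start_idx,
                end_idx=c.end_idx,
                t_mass=c.t_mass,
                p_corr=p,
            )
        )
    return out


def extract_ihr_change(
    epochs_by_participant: dict,
    cluster_window: tuple[float, float],
    reject_iqr_k: float = 1.5,
) -> pd.DataFrame:
    """Trial-wise maximum heart-rate change within a cluster window.

    For each trial, the signed extreme (maximum-magnitude) baseline-
    referenced iHR value inside the window; Tukey 1.5-IQR rejection and
    z-scoring within participant.  The caller supplies the window of the
    significant negative intercept cluster (use a configurable fallback
    window when none exists).
    """
    rows = []
    for p, ep in epochs_by_participant.items():
        m = (ep.time_axis >= cluster_window[0]) & (ep.time_axis <= cluster_window[1])
        if not m.any():
            raise ValueError("cluster window outside the epoch time axis")
        seg = ep.values[:, m]
        idx = np.argmax(np.abs(seg), axis=1)
        vals = seg[np.arange(seg.shape[0]), idx]
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        keep = (vals >= q1 - reject_iqr_k * iqr) & (vals <= q3 + reject_iqr_k * iqr)
        kept_vals = vals[keep]
        sd = kept_vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero variance of iHR change for participant {p}")
        z = (kept_vals - kept_vals.mean()) / sd
        tr_idx = ep.trial_index[keep] if ep.trial_index.size else np.flatnonzero(keep)
        for ti, v, zz in zip(tr_idx, kept_vals, z):
            rows.append(
                {"participant_id": p, "trial": int(ti), "hr_change": float(v), "hr_change_z": float(zz)}
            )
    return pd.DataFrame(rows)
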
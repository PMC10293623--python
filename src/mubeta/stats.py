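"""Mixed repeated-measures ANOVA for the 6 (ROI) x 3 (Condition) ERD/S design.

The model is a balanced split-plot ANOVA: two crossed within-subject factors
(ROI, Condition) and two crossed between-subject factors (Handedness, Sex),
with participants as the random blocking factor nested in Handedness x Sex.
Sums of squares follow the classical partition for balanced designs; every
within-subject effect is tested against the interaction of its within part
with participants, and between-subject effects against participants within
groups.

Sphericity of the within-subject covariance is not assumed: each within
stratum gets a Greenhouse-Geisser (Box) epsilon estimated from the pooled
within-group covariance of subject-level scores, and the F-test degrees of
freedom are multiplied by it. Post-hoc pairwise comparisons use the
studentized-range (Tukey) distribution on the stratum's error term.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

ROI_LEVELS = ["FL", "FR", "CL", "CR", "PL", "PR"]
CONDITION_LEVELS = ["BOTH", "LEFT", "RIGHT"]

_WITHIN = ("ROI", "Condition")
_BETWEEN = ("Handedness", "Sex")
_AXIS = {"Handedness": 0, "Sex": 1, "ROI": 3, "Condition": 4}


class DesignError(ValueError):
    """Raised when the table is not a complete balanced design."""


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # one row per effect: SS, df, F, eps, p, ...
    strata: dict  # stratum name -> {"ms": float, "df": float, "eps": float}
    data: np.ndarray  # (n_h, n_s, n_subj, n_roi, n_cond) cell values
    levels: dict  # factor -> level labels
    n_per_cell: int

    def effect(self, name: str) -> pd.Series:
        sub = self.effects[self.effects["effect"] == name]
        if sub.empty:
            raise KeyError(f"unknown effect {name!r}")
        return sub.iloc[0]


def _contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast matrix (rows orthogonal to the mean)."""
    if k < 2:
        raise ValueError("need at least 2 levels for contrasts")
    return null_space(np.ones((1, k))).T


def gg_epsilon(cov: np.ndarray, k: int) -> float:
    """Greenhouse-Geisser (Box) epsilon from a k x k within-level covariance.

    epsilon = trace(M)^2 / ((k-1) * trace(M @ M)) with M the covariance
    projected onto k-1 orthonormal contrasts; clipped to [1/(k-1), 1].
    """
    if k < 2:
        raise ValueError("epsilon needs k >= 2 levels")
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (k, k):
        raise ValueError(f"covariance must be {k}x{k}, got {cov.shape}")
    C = _contrasts(k)
    return _epsilon_from_projected(C @ cov @ C.T)


def _epsilon_from_projected(M: np.ndarray) -> float:
    d = M.shape[0]
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def _pivot(table: pd.DataFrame, dv: str) -> tuple[np.ndarray, dict]:
    """Arrange the long table into a (h, s, subj, roi, cond) array."""
    required = {"participant", "handedness", "sex", "roi", "condition", dv}
    missing = required - set(table.columns)
    if missing:
        raise DesignError(f"table is missing columns {sorted(missing)}")
    h_levels = sorted(table["handedness"].unique())
    s_levels = sorted(table["sex"].unique())
    if len(h_levels) != 2 or len(s_levels) != 2:
        raise DesignError(
            f"need 2 handedness and 2 sex levels, got {h_levels} / {s_levels}"
        )
    roi_levels = [r for r in ROI_LEVELS if r in set(table["roi"])]
    cond_levels = [c for c in CONDITION_LEVELS if c in set(table["condition"])]
    if set(table["roi"]) - set(roi_levels) or set(table["condition"]) - set(cond_levels):
        raise DesignError("unknown roi or condition labels in table")
    p, q = len(roi_levels), len(cond_levels)
    if p < 2 or q < 2:
        raise DesignError("each within factor needs >= 2 levels")

    cells: list[list[list[np.ndarray]]] = []
    n_ref = None
    for h in h_levels:
        row_s = []
        for s in s_levels:
            grp = table[(table["handedness"] == h) & (table["sex"] == s)]
            subjects = sorted(grp["participant"].unique())
            if len(subjects) < 2:
                raise DesignError(
                    f"between-cell ({h}, {s}) has {len(subjects)} participant(s); need >= 2"
                )
            if n_ref is None:
                n_ref = len(subjects)
            elif len(subjects) != n_ref:
                raise DesignError(
                    "unequal participant counts across handedness x sex cells "
                    f"({len(subjects)} vs {n_ref}); the balanced partition does not apply"
                )
            subj_arrays = []
            for subj in subjects:
                sub = grp[grp["participant"] == subj]
                piv = sub.pivot_table(index="roi", columns="condition", values=dv, aggfunc="mean")
                if piv.shape != (p, q) or piv.isna().any().any() or len(sub) != p * q:
                    raise DesignError(
                        f"participant {subj!r} does not have exactly one value per "
                        f"roi x condition cell ({p * q} expected, {len(sub)} found)"
                    )
                subj_arrays.append(piv.loc[roi_levels, cond_levels].to_numpy())
            row_s.append(subj_arrays)
        cells.append(row_s)
    X = np.asarray(cells)  # (2, 2, n, p, q)
    levels = {
        "Handedness": h_levels, "Sex": s_levels,
        "ROI": roi_levels, "Condition": cond_levels,
    }
    return X, levels


def _marg(X: np.ndarray, keep: frozenset[int]) -> np.ndarray:
    axes = tuple(ax for ax in range(X.ndim) if ax not in keep)
    return X.mean(axis=axes, keepdims=True) if axes else X


def _effect_ss(X: np.ndarray, factors: tuple[str, ...]) -> float:
    """SS of a fixed effect (subset of the four named factors) on balanced data."""
    axes = [_AXIS[f] for f in factors]
    E = np.zeros_like(X)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            sign = (-1) ** (len(axes) - r)
            E = E + sign * _marg(X, frozenset(sub))
    return float((E**2).sum())


def _error_ss(X: np.ndarray, within: tuple[str, ...]) -> float:
    """SS of the participant (x within) error stratum."""
    axes = [_AXIS[f] for f in within]
    base = frozenset({0, 1})
    E = np.zeros_like(X)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            sign = (-1) ** (len(axes) - r)
            keep = frozenset(sub)
            E = E + sign * (_marg(X, base | {2} | keep) - _marg(X, base | keep))
    return float((E**2).sum())


def _pooled_scores_cov(scores: np.ndarray) -> np.ndarray:
    """Covariance of subject-level score vectors pooled within between-groups.

    ``scores`` has shape (n_h, n_s, n_subj, k)."""
    nh, ns, n, k = scores.shape
    dev = scores - scores.mean(axis=2, keepdims=True)
    flat = dev.reshape(-1, k)
    return flat.T @ flat / (nh * ns * (n - 1))


def mixed_rm_anova(table: pd.DataFrame, dv: str = "erds_percent") -> AnovaResult:
    """Fit the 2 (Handedness) x 2 (Sex) x ROI x Condition mixed RM-ANOVA.

    Returns the full effect table with uncorrected and Greenhouse-Geisser
    corrected p-values. Missing or unbalanced cells raise :class:`DesignError`.
    """
    X, levels = _pivot(table, dv)
    nh, ns, n, p, q = X.shape

    df_between_err = nh * ns * (n - 1)
    strata: dict[str, dict] = {
        "between": {"ss": _error_ss(X, ()), "df": df_between_err, "eps": 1.0},
        "ROI": {"ss": _error_ss(X, ("ROI",)), "df": df_between_err * (p - 1)},
        "Condition": {"ss": _error_ss(X, ("Condition",)), "df": df_between_err * (q - 1)},
        "ROI*Condition": {
            "ss": _error_ss(X, ("ROI", "Condition")),
            "df": df_between_err * (p - 1) * (q - 1),
        },
    }

    # Greenhouse-Geisser epsilon per within stratum from subject-level scores
    roi_scores = X.mean(axis=4)  # (nh, ns, n, p)
    cond_scores = X.mean(axis=3)  # (nh, ns, n, q)
    strata["ROI"]["eps"] = gg_epsilon(_pooled_scores_cov(roi_scores), p)
    strata["Condition"]["eps"] = gg_epsilon(_pooled_scores_cov(cond_scores), q)
    Cp, Cq = _contrasts(p), _contrasts(q)
    Cpq = np.kron(Cp, Cq)
    cov_pq = _pooled_scores_cov(X.reshape(nh, ns, n, p * q))
    strata["ROI*Condition"]["eps"] = _epsilon_from_projected(Cpq @ cov_pq @ Cpq.T)

    for s in strata.values():
        s["ms"] = s["ss"] / s["df"]

    k_of = {"Handedness": nh, "Sex": ns, "ROI": p, "Condition": q}

    def df_effect(factors):
        out = 1
        for f in factors:
            out *= k_of[f] - 1
        return out

    def _order(f: str) -> tuple:
        if f in _WITHIN:
            return (0, _WITHIN.index(f))
        return (1, _BETWEEN.index(f))

    effect_sets = []
    for r in (1, 2, 3, 4):
        for combo in combinations(("ROI", "Condition", "Handedness", "Sex"), r):
            effect_sets.append(tuple(sorted(combo, key=_order)))

    rows = []
    for factors in effect_sets:
        within_part = tuple(f for f in factors if f in _WITHIN)
        stratum = "*".join(sorted(within_part, key=_WITHIN.index)) or "between"
        ss = _effect_ss(X, factors)
        df1 = df_effect(factors)
        err = strata[stratum]
        F = (ss / df1) / err["ms"] if err["ms"] > 0 else np.inf
        eps = err["eps"]
        rows.append(
            {
                "effect": "*".join(factors),
                "stratum": stratum,
                "SS": ss,
                "df1": df1,
                "df2": err["df"],
                "F": F,
                "epsilon": eps,
                "df1_gg": eps * df1,
                "df2_gg": eps * err["df"],
                "p_uncorrected": float(f_dist.sf(F, df1, err["df"])),
                "p_gg": float(f_dist.sf(F, eps * df1, eps * err["df"])),
            }
        )
    effects = pd.DataFrame(rows)
    return AnovaResult(effects=effects, strata=strata, data=X, levels=levels, n_per_cell=n)


def ar1_covariance(k: int, rho: float, var_min: float = 1.0, var_max: float = 1.0) -> np.ndarray:
    """AR(1)-correlated covariance with linearly increasing variances.

    With rho != 0 or unequal variances the matrix violates sphericity, which
    is the regime the Greenhouse-Geisser correction is built for."""
    sd = np.sqrt(np.linspace(var_min, var_max, k))
    lags = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    return np.outer(sd, sd) * rho**lags


def simulate_long_design(
    n_per_cell: int,
    seed: int,
    roi_cov: np.ndarray | None = None,
    cond_cov: np.ndarray | None = None,
    subject_sd: float = 2.0,
    roi_effect: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a balanced long-format table from a multivariate-normal model.

    Each participant contributes one 6 x 3 (ROI x Condition) cell matrix:
    a random subject intercept plus correlated noise with covariance
    ``kron(roi_cov, cond_cov)`` (defaults: moderately nonspherical AR(1)
    structures). ``roi_effect`` optionally adds fixed per-ROI shifts; with it
    left at None the data obey the global null. Intended for validating the
    ANOVA's error rates.
    """
    roi_cov = ar1_covariance(6, 0.5, 1.0, 2.5) if roi_cov is None else roi_cov
    cond_cov = ar1_covariance(3, 0.3, 1.0, 1.6) if cond_cov is None else cond_cov
    L = np.linalg.cholesky(np.kron(roi_cov, cond_cov))
    shift = np.zeros(6) if roi_effect is None else np.asarray(roi_effect, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for h in ("left", "right"):
        for s in ("female", "male"):
            for _ in range(n_per_cell):
                pid += 1
                y = rng.normal(0.0, subject_sd) + L @ rng.standard_normal(18)
                y = y.reshape(6, 3) + shift[:, None]
                for i, roi in enumerate(ROI_LEVELS):
                    for j, cond in enumerate(CONDITION_LEVELS):
                        rows.append(
                            (f"P{pid:03d}", h, s, roi, cond, y[i, j])
                        )
    return pd.DataFrame(
        rows,
        columns=["participant", "handedness", "sex", "roi", "condition", "erds_percent"],
    )


def emmeans(result: AnovaResult, effect: str) -> pd.DataFrame:
    """Estimated marginal means with standard errors for an effect.

    For the balanced design these are raw means averaged over non-focal
    factors. The SE is the standard error of the level mean across the
    participants contributing to it (subject-level scores pooled over the
    non-focal within factors; groups pooled for purely within effects).
    """
    factors = effect.split("*")
    for f in factors:
        if f not in _AXIS:
            raise KeyError(f"unknown factor {f!r} in effect {effect!r}")
    X = result.data
    # subject-level scores at the focal within levels
    within = [f for f in factors if f in _WITHIN]
    drop_within = [_AXIS[f] for f in _WITHIN if f not in within]
    scores = X.mean(axis=tuple(drop_within), keepdims=True) if drop_within else X

    level_lists = [result.levels[f] for f in factors]
    rows = []
    for idx in np.ndindex(*[len(lv) for lv in level_lists]):
        sel = [slice(None)] * 5
        for f, i in zip(factors, idx):
            sel[_AXIS[f]] = i
        vals = scores[tuple(sel)]
        # collapse remaining between axes and squeeze within singleton axes
        per_subject = vals.reshape(-1)
        mean = float(per_subject.mean())
        se = float(per_subject.std(ddof=1) / np.sqrt(per_subject.size)) if per_subject.size > 1 else 0.0
        row = {f: result.levels[f][i] for f, i in zip(factors, idx)}
        row.update(mean=mean, se=se, n=per_subject.size)
        rows.append(row)
    return pd.DataFrame(rows)


def tukey_pairwise(
    means: pd.DataFrame,
    error_df: float,
    error_ms: float,
    n_per_mean: int,
    level_col: str | None = None,
) -> pd.DataFrame:
    """All pairwise comparisons of marginal means with Tukey-corrected p.

    p-values come from the studentized-range distribution with ``k`` means
    and the error stratum's degrees of freedom; ``t = diff / sqrt(2*MS/n)``
    and ``q = t * sqrt(2)``. Symmetric in pair order.
    """
    if level_col is None:
        level_col = [c for c in means.columns if c not in ("mean", "se", "n")][0]
    k = len(means)
    if k < 2:
        raise ValueError("need >= 2 levels for pairwise comparisons")
    se_diff = np.sqrt(2.0 * error_ms / n_per_mean)
    rows = []
    for (_, a), (_, b) in combinations(means.iterrows(), 2):
        diff = a["mean"] - b["mean"]
        t = diff / se_diff if se_diff > 0 else np.inf * np.sign(diff)
        qstat = abs(t) * np.sqrt(2.0)
        pval = float(np.clip(studentized_range.sf(qstat, k, error_df), 0.0, 1.0))
        rows.append(
            {
                "level_a": a[level_col], "level_b": b[level_col],
                "diff": diff, "t": t, "p_tukey": pval,
            }
        )
    return pd.DataFrame(rows)


def posthoc_for_effect(result: AnovaResult, effect: str) -> pd.DataFrame:
    """Tukey pairwise table for a main effect, using its error stratum."""
    factors = effect.split("*")
    means = emmeans(result, effect)
    within = [f for f in factors if f in _WITHIN]
    stratum = "*".join(sorted(within, key=_WITHIN.index)) or "between"
    err = result.strata[stratum]
    n_per_mean = int(means["n"].iloc[0])
    if within:
        # other within levels multiply the observations behind each mean
        for f in _WITHIN:
            if f not in factors:
                n_per_mean *= len(result.levels[f])
    else:
        n_per_mean *= len(result.levels["ROI"]) * len(result.levels["Condition"])
    level_cols = [c for c in means.columns if c not in ("mean", "se", "n")]
    if len(level_cols) > 1:
        means = means.assign(
            _level=means[level_cols].astype(str).agg(" ".join, axis=1)
        )[["_level", "mean", "se", "n"]].rename(columns={"_level": "level"})
    return tukey_pairwise(means, err["df"], err["ms"], n_per_mean)
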
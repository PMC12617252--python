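"""Group statistics: permutation ANOVA, gated post-hoc t-tests,
Benjamini-Hochberg FDR, and Shapiro-Wilk-gated Spearman correlations.

The scheme mirrors a three-group cross-sectional design: a one-way ANOVA
F statistic whose p-value comes from unrestricted group-label
permutations (add-one convention, so p is never zero), pairwise
two-sample t-tests run only when the main effect is significant, BH-FDR
applied within declared families, and rank correlations between clinical
covariates and the measures that survived the group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GateError",
    "AnovaResult",
    "perm_anova",
    "perm_anova_table",
    "posthoc_pairwise",
    "fdr_bh",
    "shapiro_report",
    "gated_spearman",
]


class GateError(RuntimeError):
    """Post-hoc tests were requested without a significant main effect."""


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    n_perm: int


def _f_stats(X: np.ndarray, onehot: np.ndarray, group_n: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each row of X given a fixed one-hot label matrix."""
    N = X.shape[1]
    k = onehot.shape[1]
    # center each row: leaves F unchanged and avoids the catastrophic
    # cancellation of the raw sum-of-squares shortcut
    Xc = X - X.mean(axis=1, keepdims=True)
    S = Xc @ onehot  # row x group sums of centered values
    ssb = (S * S / group_n).sum(axis=1)
    sst = (Xc * Xc).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    return F


def _labels_onehot(labels: np.ndarray):
    cats, codes = np.unique(labels, return_inverse=True)
    k = cats.size
    onehot = np.zeros((codes.size, k))
    onehot[np.arange(codes.size), codes] = 1.0
    return cats, onehot, onehot.sum(axis=0)


def perm_anova_table(
    X,
    labels,
    n_perm: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Permutation one-way ANOVA for each row of ``X`` (rows = measures,
    columns = subjects), sharing one set of label permutations across rows.

    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)`` — the add-one
    convention, so the smallest attainable p-value is ``1/(n_perm+1)``.
    Rows with zero total variance get ``F = p = NaN`` (flagged; callers
    exclude them from FDR families).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[1] != labels.size:
        raise ValueError("X columns must match the number of labels")
    cats, onehot, group_n = _labels_onehot(labels)
    if cats.size < 2 or np.any(group_n < 2):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    F_obs = _f_stats(X, onehot, group_n)
    rng = np.random.default_rng(seed)
    N = labels.size
    exceed = np.zeros(X.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(N)
        F_perm = _f_stats(X[:, perm], onehot, group_n)
        exceed += np.where(np.isnan(F_perm) | np.isnan(F_obs), 0.0, F_perm >= F_obs)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(np.isnan(F_obs), np.nan, p)
    return pd.DataFrame({"F": F_obs, "p": p, "n_perm": n_perm})


def perm_anova(groups, n_perm: int = 1000, seed=None) -> AnovaResult:
    """Permutation one-way ANOVA for one measure given per-group value arrays."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    x = np.concatenate(groups)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    row = perm_anova_table(x[None, :], labels, n_perm=n_perm, seed=seed).iloc[0]
    return AnovaResult(float(row["F"]), float(row["p"]), n_perm)


def posthoc_pairwise(
    groups: dict,
    main_p: float,
    pairs=None,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided two-sample t-tests for each group pair, gated on the main
    effect.

    The significance gate (main-effect ``p < alpha``) is enforced here:
    calling with a non-significant main effect raises :class:`GateError`.
    ``equal_var=True`` gives the classical pooled-variance post-hoc
    companion of the ANOVA; Welch is available via ``equal_var=False``.
    """
    if not (main_p < alpha):
        raise GateError(
            f"post-hoc t-tests require a significant main effect "
            f"(p={main_p:.4g} >= alpha={alpha})"
        )
    names = list(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(np.asarray(groups[a], float),
                             np.asarray(groups[b], float),
                             equal_var=equal_var)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up within one family.

    Returns ``(reject, qvals)``.  NaN p-values (flagged tests) are
    excluded from the family and propagate NaN q-values; an empty family
    returns empty arrays.
    """
    p = np.asarray(pvals, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if valid.sum() == 0:
        return reject, qvals
    rej, qv, _, _ = multipletests(p[valid], alpha=q, method="fdr_bh")
    reject[valid] = rej
    qvals[valid] = qv
    return reject, qvals


def shapiro_report(clinical: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk normality test for each clinical variable (column).

    Recorded as metadata for the correlation analysis: associations are
    reported with Spearman rank correlations throughout, and this table
    documents the non-normality that motivates the rank-based choice.
    """
    rows = []
    for col in clinical.columns:
        v = clinical[col].dropna().to_numpy(dtype=float)
        if v.size < 3 or np.ptp(v) == 0:
            rows.append({"variable": col, "W": np.nan, "p": np.nan,
                         "n": int(v.size), "normal": False})
            continue
        W, p = sps.shapiro(v)
        rows.append({"variable": col, "W": float(W), "p": float(p),
                     "n": int(v.size), "normal": bool(p >= 0.05)})
    return pd.DataFrame(rows)


def gated_spearman(
    clinical: pd.DataFrame,
    measures: pd.DataFrame,
    group: str,
    q: float = 0.05,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlations between clinical variables and selected measures
    within one group, FDR-corrected per clinical variable.

    ``measures`` must contain only measures that survived the between-group
    analyses (the data-driven selection is enforced by the pipeline layer).
    Rows of ``clinical`` and ``measures`` are aligned subjects.  For each
    (variable, measure) pair the tie-corrected Spearman rho and p are
    computed on pairwise-complete observations; pairs with fewer than
    ``min_n`` observations or zero variance are flagged (NaN statistics)
    and excluded from the FDR family.  The family is the set of candidate
    measures within one group x clinical variable, each corrected at level
    ``q``; results with raw ``p < 0.1`` that do not survive FDR are
    labelled "marginal", never promoted.
    """
    if clinical.shape[0] != measures.shape[0]:
        raise ValueError("clinical and measures must cover the same subjects")
    shapiro = shapiro_report(clinical)
    shapiro_p = dict(zip(shapiro["variable"], shapiro["p"]))
    out = []
    for var in clinical.columns:
        cv = clinical[var].to_numpy(dtype=float)
        rows = []
        for meas in measures.columns:
            mv = measures[meas].to_numpy(dtype=float)
            ok = np.isfinite(cv) & np.isfinite(mv)
            n = int(ok.sum())
            if n < min_n or np.ptp(cv[ok]) == 0 or np.ptp(mv[ok]) == 0:
                rows.append({"group": group, "variable": var, "measure": meas,
                             "rho": np.nan, "p": np.nan, "n": n,
                             "shapiro_p": shapiro_p.get(var, np.nan),
                             "flag": "insufficient-data"})
                continue
            rho, p = sps.spearmanr(cv[ok], mv[ok])
            rows.append({"group": group, "variable": var, "measure": meas,
                         "rho": float(rho), "p": float(p), "n": n,
                         "shapiro_p": shapiro_p.get(var, np.nan), "flag": ""})
        fam = pd.DataFrame(rows)
        reject, qv = fdr_bh(fam["p"].to_numpy(), q=q)
        fam["q"] = qv
        fam["significant"] = reject
        fam["marginal"] = (~reject) & (fam["p"] < 0.1)
        out.append(fam)
    return pd.concat(out, ignore_index=True)
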
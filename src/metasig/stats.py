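"""Group comparison statistics: Mann-Whitney U + Benjamini-Hochberg FDR over
taxa, genes and signature pairs, and Spearman correlation with severity.

Tests are two-sided throughout. Each reported family (taxa per level, genes,
pairs per level, severity correlations) is corrected separately, and
features detected in fewer than half of the samples are excluded before
testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .profiling import prevalence_filter

SCORE_NAMES = ("CES-D", "GAD-7", "HAMD-17")


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    U counts pairs with x_i > y_j plus half the ties. The p-value is exact
    (full null enumeration) when min(n) <= 8 and the data are tie-free,
    otherwise a normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return len(x) * len(y) / 2.0, 1.0
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # tie-corrected variance of 0: no evidence either way
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def mann_whitney_enumerate(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by brute-force enumeration of labelings.

    Reference implementation for small tie-free samples: every C(n1+n2, n1)
    assignment of the pooled values to the first group is enumerated and the
    p-value is the fraction with min-tail U at least as extreme.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        xs = np.asarray(xs)[:, None]
        ys = np.asarray(ys)[None, :]
        return float((xs > ys).sum() + 0.5 * (xs == ys).sum())

    u_obs = u_stat(x, y)
    u_mid = len(x) * len(y) / 2.0
    extreme = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - u_mid) >= abs(u_obs - u_mid) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TestResult:
    feature: str
    U: float
    p: float
    q: float
    median_control: float
    median_case: float
    direction: int  # sign of (median_case - median_control)
    significant: bool


def compare_features(matrix: pd.DataFrame, group_labels: pd.Series,
                     case: str = "PwD", control: str = "HC",
                     min_prevalence: float = 0.5,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Prevalence filter, per-feature Mann-Whitney, BH over the surviving family.

    ``matrix`` is feature x sample; ``group_labels`` maps sample id to group.
    Returns a DataFrame indexed by feature with U, p, q, group medians,
    direction, and a q < alpha significance flag.
    """
    labels = group_labels.loc[matrix.columns]
    case_cols = matrix.columns[labels == case]
    ctrl_cols = matrix.columns[labels == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    kept = prevalence_filter(matrix, min_prevalence)
    rows = []
    for feature, values in kept.iterrows():
        x = values[case_cols].to_numpy(dtype=float)
        y = values[ctrl_cols].to_numpy(dtype=float)
        u, p = mann_whitney(x, y)
        rows.append((feature, u, p, float(np.median(y)), float(np.median(x))))
    if not rows:
        return pd.DataFrame(columns=["U", "p", "q", "median_control", "median_case",
                                     "direction", "significant"])
    out = pd.DataFrame(rows, columns=["feature", "U", "p", "median_control",
                                      "median_case"]).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.sign(out["median_case"] - out["median_control"]).astype(int)
    out["significant"] = out["q"] < alpha
    return out[["U", "p", "q", "median_control", "median_case", "direction",
                "significant"]]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; (rho, p).

    p by exact permutation enumeration when n <= 7, else the t
    approximation. Constant input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= 7:
        count = total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def correlate_severity(signature_table: pd.DataFrame, scores_table: pd.DataFrame,
                       score_names=SCORE_NAMES, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each signature pair with each severity score.

    ``signature_table`` is pair x sample (MultiIndex (taxon, gene) or plain
    index); ``scores_table`` is sample x score. Negative rho means lower
    abundance associates with higher severity. Pairs with constant abundance
    are flagged missing and excluded from the BH family.
    """
    missing = set(signature_table.columns) - set(scores_table.index)
    if missing:
        raise ValueError(f"samples without scores: {sorted(missing)[:5]}")
    scores = scores_table.loc[list(signature_table.columns)]
    rows = []
    for pair, values in signature_table.iterrows():
        v = values.to_numpy(dtype=float)
        for score in score_names:
            rho, p = spearman(v, scores[score].to_numpy(dtype=float))
            rows.append({"pair": pair if isinstance(pair, str) else "; ".join(pair),
                         "score": score, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
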
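"""Community diversity: Shannon index, Bray-Curtis dissimilarity, PERMANOVA.

Alpha diversity is Shannon's H in nats by default. Beta diversity is the
Bray-Curtis dissimilarity between per-sample abundance vectors, and group
structure in the resulting distance matrix is tested with a permutation
PERMANOVA (pseudo-F over permuted group labels, add-one p-value estimator,
so the smallest attainable p with 999 permutations is 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix


def shannon(abundance_vector, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over normalized nonzero entries.

    Natural log by default; pass ``base`` for other logarithms.
    """
    p = np.asarray(abundance_vector, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between sample columns.

    ``profiles`` is a feature x sample table. d(x, y) = sum|x-y| / sum(x+y),
    which lies in [0, 1] and is invariant to jointly rescaling both vectors.
    """
    data = profiles.to_numpy(dtype=float).T  # samples x features
    if (data < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = data.sum(axis=1) == 0
    if zero.any():
        bad = list(profiles.columns[zero])
        raise ValueError(f"all-zero sample(s) make Bray-Curtis undefined: {bad}")
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in profiles.columns])


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    degenerate: bool = False  # SS_within == 0: F unbounded, p reported at floor


def _ss_terms(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        members = np.flatnonzero(labels == g)
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    return ss_total, ss_within


def permanova(distance_matrix, group_labels, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with label permutations.

    pseudo-F = ((SS_total - SS_within) / (a - 1)) / (SS_within / (N - a))
    with SS terms computed from squared distances; the p-value uses the
    add-one estimator (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if isinstance(distance_matrix, DistanceMatrix):
        d = distance_matrix.data
        ids = list(distance_matrix.ids)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        ids = list(range(d.shape[0]))
    labels = np.asarray(
        group_labels.loc[ids] if isinstance(group_labels, pd.Series) else group_labels)
    if labels.shape[0] != d.shape[0]:
        raise ValueError("labels do not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    n, a = d.shape[0], len(groups)
    d2 = d ** 2
    ss_total, ss_within = _ss_terms(d2, labels, groups)
    if ss_within == 0:
        return PermanovaResult(np.inf, 1.0 / (1 + n_permutations), n_permutations,
                               degenerate=True)

    def f_stat(ss_w):
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    # vectorized permutations: SS_within from group indicator matrices
    perm = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm_labels = labels[perm]  # (P, n)
    ss_w_perm = np.zeros(n_permutations)
    for g, n_g in zip(groups, counts):
        ind = (perm_labels == g).astype(float)  # (P, n)
        quad = np.einsum("pi,ij,pj->p", ind, d2, ind)  # includes diagonal=0, double-counts
        ss_w_perm += quad / (2.0 * n_g)
    with np.errstate(divide="ignore"):
        f_perm = np.where(ss_w_perm > 0,
                          ((ss_total - ss_w_perm) / (a - 1)) / (ss_w_perm / (n - a)),
                          np.inf)
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations)
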
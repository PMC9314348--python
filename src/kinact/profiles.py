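"""Cross-dataset comparison of site sets and kinase activity profiles.

Two experiments can be compared at the raw-data level (Jaccard similarity of
their mapped site sets) or at the inference level (Spearman rank correlation
of their kinase activity profiles). Activity profiles from heterogeneous
samples can be placed on a common scale by quantile normalization, and
summarized across experiments by the average activity rank per kinase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "jaccard_sites",
    "spearman_profiles",
    "quantile_normalize",
    "average_rank",
    "profile_matrix",
    "pairwise_spearman",
]


def jaccard_sites(a, b) -> float:
    """Jaccard similarity |a n b| / |a u b| of two site sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both site sets are empty")
    return len(a & b) / len(a | b)


def spearman_profiles(x: pd.Series, y: pd.Series) -> float:
    """Spearman rank correlation over the kinases shared by two profiles."""
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared kinases, have {len(shared)}")
    rho, _ = stats.spearmanr(x.loc[shared], y.loc[shared])
    return float(rho)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Standard quantile normalization across columns (samples).

    Each column's sorted values are replaced by the across-column mean of
    sorted values, reassigned by rank; ties receive the mean of the quantile
    values they span. Missing cells are rejected.
    """
    if m.isna().any().any():
        raise ValueError("profile matrix contains missing cells")
    values = m.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        # interpolate fractional (tie) ranks onto the reference distribution
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def average_rank(profiles) -> pd.Series:
    """Mean activity rank per kinase across experiments.

    Within each experiment kinases are ranked ascending by Mann-Whitney p
    (rank 1 = most active; ties get the minimum rank); the output is the mean
    rank per kinase over all experiments.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    shared = None
    for p in profiles:
        idx = set(p.table.index)
        shared = idx if shared is None else shared & idx
    shared = sorted(shared)
    if not shared:
        raise ValueError("profiles share no kinases")
    ranks = []
    for p in profiles:
        mw = p.table.loc[shared, "mw_p"].to_numpy(dtype=float)
        ranks.append(stats.rankdata(mw, method="min"))
    out = pd.Series(np.mean(ranks, axis=0), index=pd.Index(shared, name="kinase"))
    return out.sort_values(kind="stable")


def profile_matrix(profiles, column: str = "score") -> pd.DataFrame:
    """Stack activity profiles into a kinase x sample matrix."""
    cols = {}
    for p in profiles:
        cols[p.condition_name] = p.table[column]
    return pd.DataFrame(cols)


def pairwise_spearman(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman correlation between sample columns."""
    samples = list(matrix.columns)
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            rho = spearman_profiles(matrix[a], matrix[b])
            out.loc[a, b] = out.loc[b, a] = rho
    return out
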
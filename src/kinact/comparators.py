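"""Quantification-based comparator scores: KSEA and KARP.

Both methods score kinases against an annotation set (kinase -> known or
predicted substrate sites) using the experiment's quantitative values, in
contrast to the binary-evidence ensemble approach of :mod:`.inference`.

KSEA z-score for kinase ``k``::

    z = (s_bar - p_bar) * sqrt(m) / delta

where ``s_bar`` is the mean log2 fold change over the kinase's identified
substrates, ``p_bar`` the dataset mean, ``m`` the identified substrate count
and ``delta`` the dataset standard deviation. Significance is a right-tailed
standard-normal test with Benjamini-Hochberg correction.

KARP K-score for kinase ``k``::

    K = (sum_alpha / sum_beta) * (m / t)**0.5 * 1e6

where ``sum_alpha`` sums the normalized intensities of the kinase's
identified substrates, ``sum_beta`` sums over all ``n`` quantified sites,
``m`` is the identified substrate count and ``t`` the kinase's total
annotated substrate count. Between conditions, kinases are ranked by the
magnitude of the K-score difference, with the sign giving the direction of
the activity change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import canonicalize_site, _read_delimited

__all__ = [
    "AnnotationSet",
    "QuantExperiment",
    "ksea_scores",
    "karp_kscore",
    "karp_rank_change",
]


class AnnotationSet:
    """Kinase -> annotated substrate-site sets (``t`` totals included)."""

    def __init__(self, substrates: dict):
        clean = {}
        for kinase, sites in substrates.items():
            sites = frozenset(sites)
            if not sites:
                raise ValueError(f"kinase {kinase!r} has an empty substrate set")
            clean[str(kinase)] = sites
        if not clean:
            raise ValueError("annotation set is empty")
        self.substrates = clean
        self.t_total = {k: len(v) for k, v in clean.items()}

    @property
    def kinases(self) -> list:
        return sorted(self.substrates)

    @classmethod
    def from_file(cls, path, sep=None) -> "AnnotationSet":
        df = _read_delimited(path, sep)
        required = {"kinase", "accession", "residue", "position"}
        if not required <= set(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        subs: dict = {}
        for _, row in df.iterrows():
            key = canonicalize_site(row["accession"], row["residue"], int(row["position"])).key
            subs.setdefault(str(row["kinase"]), set()).add(key)
        return cls(subs)


@dataclass
class QuantExperiment:
    """Quantified sites: log2 fold changes and/or nonnegative intensities."""

    log2fc: pd.Series | None = None  # site key -> log2FC
    intensity: pd.Series | None = None  # site key -> normalized intensity

    def __post_init__(self):
        if self.log2fc is not None:
            self.log2fc = pd.Series(self.log2fc, dtype=float).dropna()
        if self.intensity is not None:
            self.intensity = pd.Series(self.intensity, dtype=float).dropna()
            if (self.intensity < 0).any():
                raise ValueError("intensities must be nonnegative")

    @property
    def n_sites(self) -> int:
        if self.log2fc is not None:
            return len(self.log2fc)
        return len(self.intensity)


def ksea_scores(
    q: QuantExperiment, ann: AnnotationSet, tail: str = "right"
) -> pd.DataFrame:
    """KSEA z-scores and (BH-corrected) p-values for every covered kinase.

    Kinases with no identified substrates (``m = 0``) are omitted. ``tail``
    selects the significance test on z: ``"right"`` (the published default)
    or ``"two-sided"``.
    """
    if q.log2fc is None:
        raise ValueError("KSEA requires log2 fold changes")
    fc = q.log2fc
    if len(fc) < 2:
        raise ValueError("need at least 2 quantified sites")
    p_bar = float(fc.mean())
    delta = float(fc.std(ddof=0))
    if delta == 0:
        raise ValueError("degenerate dataset: zero standard deviation of log2FC")

    rows = {}
    for kinase in ann.kinases:
        found = fc.index.intersection(ann.substrates[kinase])
        m = len(found)
        if m == 0:
            continue
        s_bar = float(fc.loc[found].mean())
        z = (s_bar - p_bar) * np.sqrt(m) / delta
        rows[kinase] = (z, m)
    if not rows:
        return pd.DataFrame(columns=["z", "p_raw", "p_adj", "m"])

    table = pd.DataFrame.from_dict(rows, orient="index", columns=["z", "m"])
    if tail == "right":
        table["p_raw"] = stats.norm.sf(table["z"])
    elif tail == "two-sided":
        table["p_raw"] = 2 * stats.norm.sf(np.abs(table["z"]))
    else:
        raise ValueError(f"tail must be 'right' or 'two-sided', got {tail!r}")
    table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    table.index.name = "kinase"
    return table[["z", "p_raw", "p_adj", "m"]]


def karp_kscore(q: QuantExperiment, ann: AnnotationSet, kinase: str) -> float:
    """KARP K-score of one kinase from single-sample normalized intensities."""
    if q.intensity is None:
        raise ValueError("KARP requires intensities")
    if kinase not in ann.substrates:
        raise KeyError(f"kinase {kinase!r} not in the annotation set")
    t = ann.t_total[kinase]
    if t == 0:
        raise ValueError(f"kinase {kinase!r} has no annotated substrates")
    total = float(q.intensity.sum())
    if total <= 0:
        raise ValueError("total intensity over all sites must be positive")
    found = q.intensity.index.intersection(ann.substrates[kinase])
    m = len(found)
    if m == 0:
        return 0.0
    alpha = float(q.intensity.loc[found].sum())
    return (alpha / total) * np.sqrt(m / t) * 1e6


def karp_all_kscores(q: QuantExperiment, ann: AnnotationSet) -> pd.Series:
    """K-scores for every annotated kinase (convenience wrapper)."""
    return pd.Series(
        {k: karp_kscore(q, ann, k) for k in ann.kinases}, name="K"
    )


def karp_rank_change(K_condition: pd.Series, K_control: pd.Series) -> pd.DataFrame:
    """Rank kinases by the magnitude of their K-score change between conditions.

    Positive ``delta_K`` indicates increased activity in the condition.
    """
    shared = K_condition.index.intersection(K_control.index)
    if len(shared) == 0:
        raise ValueError("conditions share no kinases")
    delta = (K_condition.loc[shared] - K_control.loc[shared]).astype(float)
    out = pd.DataFrame(
        {
            "delta_K": delta,
            "direction": np.where(delta > 0, "increase", np.where(delta < 0, "decrease", "unchanged")),
        }
    )
    out = out.reindex(delta.abs().sort_values(ascending=False, kind="stable").index)
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "kinase"
    return out
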
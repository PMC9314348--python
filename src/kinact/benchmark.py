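"""Benchmarking: hit/accuracy statistics and data-loss attack experiments.

Accuracy over perturbation conditions uses the hit fraction

    P_hit = hits / (hits + misses)

computed *per kinase* first (over the conditions perturbing that kinase) and
then averaged unweighted over kinases, so that heavily re-studied kinases do
not dominate the global figure.

The data-loss experiment removes sites from an evidence set either uniformly
at random or *targeted* — most-studied sites (highest compendia count) first,
at random within a tier — over a 5%..95% grid in 5% steps with five
replicates per point. From the resulting mean false-discovery-rate curves:

- *tolerable loss*: the largest removal percentage up to which a majority
  (>= 3 of 5) of replicates still show significant activity (FDR <= 0.05);
- *sensitivity to data loss*: trapezoidal area under the random-removal mean
  FDR curve over 0-50% removal (the 0% point is the full-data FDR);
- *sensitivity to study bias*: the area between the targeted and random mean
  FDR curves over the same range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reference import EvidenceSet, Phosphoproteome

__all__ = [
    "BenchmarkCondition",
    "LossCurve",
    "hit_by_rank",
    "hit_by_significance",
    "phit_kinase",
    "phit_global",
    "phit_pooled",
    "reduce_experiment",
    "loss_curves",
    "tolerable_loss",
    "sensitivity_metrics",
    "REMOVAL_GRID",
    "NO_PREDICTION",
]

REMOVAL_GRID = tuple(range(5, 100, 5))
N_REPLICATES = 5
#: Sentinel FDR recorded when a scorer cannot produce a prediction
#: (e.g. every annotated substrate was removed).
NO_PREDICTION = np.nan


@dataclass
class BenchmarkCondition:
    """One perturbation condition with its expected responding kinases."""

    name: str
    evidence: object  # EvidenceSet or QuantExperiment
    expected_kinases: frozenset
    direction: str = "activated"

    def __post_init__(self):
        self.expected_kinases = frozenset(self.expected_kinases)
        if not self.expected_kinases:
            raise ValueError("expected_kinases must be non-empty")
        if self.direction not in ("activated", "inhibited"):
            raise ValueError(f"direction must be activated/inhibited, got {self.direction!r}")


def hit_by_rank(scores: pd.Series, expected: str, top_k: int = 10) -> bool:
    """Is the expected kinase in the top ``top_k`` by descending score?

    Ties use competition (min) ranking, so a tie group straddling the cutoff
    counts as a hit. An expected kinase absent from the score table counts as
    a miss (with a warning), since algorithms differ in kinase coverage.
    """
    if expected not in scores.index:
        warnings.warn(f"expected kinase {expected!r} has no score; counted as miss", stacklevel=2)
        return False
    ranks = stats.rankdata(-scores.to_numpy(), method="min")
    return bool(ranks[scores.index.get_loc(expected)] <= top_k)


def hit_by_significance(significance: pd.Series, expected: str, alpha: float = 0.05) -> bool:
    """Is the expected kinase's significance measure (FPR or adjusted p) <= alpha?"""
    if expected not in significance.index:
        warnings.warn(f"expected kinase {expected!r} has no significance value; counted as miss", stacklevel=2)
        return False
    value = significance[expected]
    return bool(np.isfinite(value) and value <= alpha)


def phit_kinase(outcomes) -> float:
    """Per-kinase accuracy: hits / (hits + misses) over that kinase's conditions."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes for kinase")
    return sum(bool(o) for o in outcomes) / len(outcomes)


def phit_global(per_kinase: dict) -> float:
    """Global accuracy: unweighted mean of per-kinase hit fractions."""
    if not per_kinase:
        raise ValueError("no per-kinase accuracies")
    return float(np.mean(list(per_kinase.values())))


def phit_pooled(outcomes_by_kinase: dict) -> float:
    """Pooled hit fraction over all conditions (kinases weighted by condition
    count) — reported alongside the per-kinase average for comparison."""
    all_outcomes = [o for outcomes in outcomes_by_kinase.values() for o in outcomes]
    if not all_outcomes:
        raise ValueError("no outcomes")
    return sum(bool(o) for o in all_outcomes) / len(all_outcomes)


def reduce_experiment(
    ev: EvidenceSet,
    proteome: Phosphoproteome,
    percent: float,
    mode: str = "random",
    seed: int = 0,
) -> EvidenceSet:
    """Remove a percentage of evidence sites at random or by targeted attack.

    ``random`` removes uniformly. ``targeted`` removes from the most-studied
    tier (highest compendia count) first, uniformly at random within a tier,
    descending until the removal count (round-half-to-even of
    ``percent * |ev| / 100``) is met.
    """
    if not 0 <= percent <= 95:
        raise ValueError(f"percent must be in [0, 95], got {percent}")
    if mode not in ("random", "targeted"):
        raise ValueError(f"mode must be 'random' or 'targeted', got {mode!r}")
    sites = sorted(ev.sites)
    n_remove = int(np.round(percent * len(sites) / 100.0))
    if n_remove == 0:
        return ev
    rng = np.random.default_rng(seed)
    if mode == "random":
        removed = set(rng.choice(sites, size=n_remove, replace=False))
    else:
        tiers: dict = {}
        for s in sites:
            tiers.setdefault(proteome.compendia_count(s), []).append(s)
        removed = set()
        for count in sorted(tiers, reverse=True):
            need = n_remove - len(removed)
            if need <= 0:
                break
            tier = tiers[count]
            if len(tier) <= need:
                removed |= set(tier)
            else:
                removed |= set(rng.choice(tier, size=need, replace=False))
    kept = frozenset(ev.sites) - removed
    return EvidenceSet.from_sites(
        f"{ev.condition_name}::{mode}-{percent}pct", kept, ev.residue_class, proteome
    )


@dataclass
class LossCurve:
    """FDR of the expected kinase as a function of data loss.

    ``replicate_fdr`` maps grid percent -> array of 5 replicate FDR values;
    ``full_fdr`` is the 0%-removal (full data) FDR shared by both modes.
    """

    mode: str
    replicate_fdr: dict
    full_fdr: float

    @property
    def removal_grid(self) -> tuple:
        return tuple(sorted(self.replicate_fdr))

    def mean_fdr(self, percent: float) -> float:
        vals = np.asarray(self.replicate_fdr[percent], dtype=float)
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pct in self.removal_grid:
            for rep, fdr in enumerate(self.replicate_fdr[pct]):
                rows.append((self.mode, pct, rep, fdr))
        return pd.DataFrame(rows, columns=["mode", "percent", "replicate", "fdr"])


def loss_curves(
    cond: BenchmarkCondition,
    scorer,
    proteome: Phosphoproteome,
    expected: str | None = None,
    modes=("random", "targeted"),
    n_replicates: int = N_REPLICATES,
    seed: int = 0,
    grid=REMOVAL_GRID,
) -> dict:
    """Run the data-loss attack experiment for one condition.

    ``scorer(evidence) -> pd.Series`` must return a significance measure
    (empirical FPR or adjusted p, the algorithm's own notion of FDR) per
    kinase; a scorer failure or a missing kinase records the sentinel
    ``NO_PREDICTION``. Returns ``{mode: LossCurve}``.
    """
    expected = expected or sorted(cond.expected_kinases)[0]
    full = scorer(cond.evidence)
    if expected not in full.index or not np.isfinite(full[expected]):
        raise ValueError(
            f"scorer yields no full-data significance for {expected!r}; "
            "condition excluded from the attack experiment"
        )
    full_fdr = float(full[expected])

    curves = {}
    for mode in modes:
        replicate_fdr = {}
        for pct in grid:
            vals = []
            for rep in range(n_replicates):
                rep_seed = seed + 1000 * rep + pct
                reduced = reduce_experiment(
                    cond.evidence, proteome, pct, mode=mode, seed=rep_seed
                )
                try:
                    sig = scorer(reduced)
                    vals.append(
                        float(sig[expected]) if expected in sig.index else NO_PREDICTION
                    )
                except (ValueError, KeyError):
                    vals.append(NO_PREDICTION)
            replicate_fdr[pct] = np.asarray(vals, dtype=float)
        curves[mode] = LossCurve(mode=mode, replicate_fdr=replicate_fdr, full_fdr=full_fdr)
    return curves


def tolerable_loss(curve: LossCurve, alpha: float = 0.05) -> int:
    """Largest removal percent tolerated before a majority of replicates lose
    significance.

    The majority criterion (>= 3 of 5 replicates with FDR <= alpha) must hold
    contiguously from the smallest grid point; a transient recovery after the
    first failure does not count. Returns 0 if the majority already fails at
    the first grid point.
    """
    last_ok = 0
    for pct in curve.removal_grid:
        vals = np.asarray(curve.replicate_fdr[pct], dtype=float)
        n_sig = int(np.sum(np.nan_to_num(vals, nan=np.inf) <= alpha))
        majority = n_sig >= int(np.ceil((len(vals) + 1) / 2))
        if not majority:
            return last_ok
        last_ok = pct
    return last_ok


def sensitivity_metrics(
    random_curve: LossCurve, targeted_curve: LossCurve, max_percent: float = 50
) -> tuple:
    """Area-based sensitivity summaries over 0..``max_percent``% removal.

    Returns ``(sens_data_loss, sens_study_bias)``: the trapezoidal area under
    the random mean-FDR curve, and the area between the targeted and random
    mean-FDR curves, in percent x FDR units. The 0% point of both curves is
    the full-data FDR.
    """
    grid = [p for p in random_curve.removal_grid if p <= max_percent]
    x = np.asarray([0.0] + [float(p) for p in grid])
    y_rand = np.asarray([random_curve.full_fdr] + [random_curve.mean_fdr(p) for p in grid])
    y_targ = np.asarray([targeted_curve.full_fdr] + [targeted_curve.mean_fdr(p) for p in grid])
    sens_data_loss = float(np.trapezoid(y_rand, x))
    sens_study_bias = float(np.trapezoid(y_targ - y_rand, x))
    return sens_data_loss, sens_study_bias
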
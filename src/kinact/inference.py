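"""Kinase-activity inference: enrichment, null resampling, scoring, FPR.

The activity score for a kinase answers: *are the sites observed in this
experiment over-represented in the kinase's substrate networks, beyond what a
study-bias-matched random experiment would show?* The pipeline is:

1. **Enrichment.** For every (kinase, network) pair, a one-sided
   hypergeometric tail ``P(X >= k)`` where ``k`` is the number of evidence
   sites in the kinase's network, ``K`` the kinase's substrate count, ``n``
   the evidence size within the background and ``N`` the background
   phosphoproteome size for the residue class.
2. **Random experiments.** 150 site sets drawn uniformly from the background,
   each matching the real evidence's size and its study-bias class
   composition (low/medium/high = 0, 1-2, 3-5 compendia), scored identically.
3. **Aggregation.** A one-sided Mann-Whitney U test per kinase asks whether
   the real networks' p-values are stochastically smaller than the pooled
   random ones; the activity score is ``-log10`` of that p-value.
4. **Empirical FPR.** Each of 100 decoy iterations treats one random
   experiment as real against the remaining 149; the FPR is the fraction of
   decoy Mann-Whitney p-values at least as significant as the real one.

Scores therefore saturate at the resolution of the Mann-Whitney statistic and
must always be interpreted together with the FPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .networks import NetworkEnsemble
from .reference import BIAS_CLASSES, EvidenceSet, Phosphoproteome

__all__ = [
    "InferenceConfig",
    "EnrichmentTable",
    "RandomExperimentSet",
    "ActivityProfile",
    "hypergeom_tail",
    "enrich",
    "draw_random_experiments",
    "mw_aggregate",
    "estimate_fpr",
    "run_kstar",
    "binary_call",
]

N_RANDOM_EXPERIMENTS = 150
N_DECOYS = 100
#: Both sides at or below this size use exact Mann-Whitney enumeration.
EXACT_MW_LIMIT = 8


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable parameters of the activity-inference stage."""

    n_random: int = N_RANDOM_EXPERIMENTS
    n_decoys: int = N_DECOYS
    seed: int = 0
    #: pool random p-values across draws x networks ("pooled") or reduce each
    #: draw to its per-network median first ("draw_median")
    random_pooling: str = "pooled"
    #: count a decoy as extreme when its p is <= ("le") or < ("lt") the real p
    fpr_comparison: str = "le"

    def __post_init__(self):
        if self.random_pooling not in ("pooled", "draw_median"):
            raise ValueError(f"unknown random_pooling {self.random_pooling!r}")
        if self.fpr_comparison not in ("le", "lt"):
            raise ValueError(f"unknown fpr_comparison {self.fpr_comparison!r}")
        if self.n_decoys > self.n_random:
            raise ValueError("n_decoys cannot exceed n_random")


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts a kinase's substrates among ``n`` sites drawn without
    replacement from a background of ``N`` sites of which ``K`` belong to the
    kinase. ``k = 0`` returns exactly 1.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("all counts must be non-negative")
    if K > N or n > N:
        raise ValueError(f"K ({K}) and n ({n}) must not exceed N ({N})")
    if k > min(n, K):
        raise ValueError(f"k ({k}) cannot exceed min(n, K) = {min(n, K)}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentTable:
    """Hypergeometric p-values for one evidence set across the ensemble.

    ``pvals`` and ``k_obs`` are DataFrames (kinase x network).
    """

    pvals: pd.DataFrame
    k_obs: pd.DataFrame
    evidence_name: str
    n: int
    N: int

    @property
    def kinases(self) -> list:
        return list(self.pvals.index)


class _EnsembleIndex:
    """Boolean membership tensor for fast repeated enrichment.

    Shape (n_networks, n_kinases, background size); background site order is
    the sorted matching-class proteome index.
    """

    def __init__(self, ens: NetworkEnsemble, proteome: Phosphoproteome, residue_class: str):
        background = sorted(proteome.background(residue_class))
        self.site_pos = {k: i for i, k in enumerate(background)}
        self.background = background
        self.kinases = ens.kinases
        self.residue_class = residue_class
        self.N = len(background)
        M = np.zeros((len(ens), len(self.kinases), self.N), dtype=bool)
        for ni, net in enumerate(ens.networks):
            for ki, kinase in enumerate(self.kinases):
                idx = [self.site_pos[s] for s in net.membership[kinase] if s in self.site_pos]
                M[ni, ki, idx] = True
        self.M = M
        self.K = M.sum(axis=2)  # (n_networks, n_kinases) substrate counts

    def evidence_vector(self, sites) -> np.ndarray:
        v = np.zeros(self.N, dtype=bool)
        idx = [self.site_pos[s] for s in sites if s in self.site_pos]
        v[idx] = True
        return v

    def k_obs(self, ev_vector: np.ndarray) -> np.ndarray:
        """Observed substrate counts, shape (n_networks, n_kinases)."""
        return np.einsum("nks,s->nk", self.M, ev_vector.astype(np.int64))


def _sf_matrix(k_obs: np.ndarray, K: np.ndarray, n: int, N: int) -> np.ndarray:
    """Vectorized hypergeometric upper tails; p = 1 wherever k = 0."""
    p = stats.hypergeom.sf(k_obs - 1, N, K, n)
    return np.where(k_obs == 0, 1.0, p)


def enrich(
    ev: EvidenceSet,
    ens: NetworkEnsemble,
    proteome: Phosphoproteome,
    _index: _EnsembleIndex | None = None,
) -> EnrichmentTable:
    """Hypergeometric substrate enrichment of one evidence set, per network."""
    index = _index or _EnsembleIndex(ens, proteome, ev.residue_class)
    if ev.residue_class != index.residue_class:
        raise ValueError("evidence and ensemble residue classes differ")
    vec = index.evidence_vector(ev.sites)
    n = int(vec.sum())
    if n == 0:
        raise ValueError(
            f"evidence set {ev.condition_name!r} shares no sites with the background"
        )
    k_obs = index.k_obs(vec)  # (networks, kinases)
    pvals = _sf_matrix(k_obs, index.K, n, index.N)
    cols = list(range(k_obs.shape[0]))
    return EnrichmentTable(
        pvals=pd.DataFrame(pvals.T, index=index.kinases, columns=cols),
        k_obs=pd.DataFrame(k_obs.T, index=index.kinases, columns=cols),
        evidence_name=ev.condition_name,
        n=n,
        N=index.N,
    )


@dataclass
class RandomExperimentSet:
    """Background-sampled site sets matching the real evidence's composition."""

    draws: list  # of EvidenceSet
    class_profile: dict  # {low, medium, high} -> count

    def __len__(self) -> int:
        return len(self.draws)


def draw_random_experiments(
    ev: EvidenceSet,
    proteome: Phosphoproteome,
    n_random: int = N_RANDOM_EXPERIMENTS,
    seed: int = 0,
) -> RandomExperimentSet:
    """Draw study-bias-matched random experiments from the background.

    Each draw has exactly the real evidence's per-class site counts
    (classes low/medium/high over compendia counts 0, 1-2, 3-5), sampled
    uniformly without replacement within each class.
    """
    background = proteome.background(ev.residue_class)
    btable = proteome.table.loc[background]
    in_bg = ev.sites & set(background)
    profile = {c: 0 for c in BIAS_CLASSES}
    for s in in_bg:
        profile[proteome.bias_class(s)] += 1

    pools = {
        c: np.asarray(background[btable["bias_class"] == c]) for c in BIAS_CLASSES
    }
    for c in BIAS_CLASSES:
        if profile[c] > len(pools[c]):
            raise ValueError(
                f"background class {c!r} has {len(pools[c])} sites but the "
                f"evidence needs {profile[c]}"
            )

    rng = np.random.default_rng(seed)
    draws = []
    for i in range(n_random):
        sites = []
        for c in BIAS_CLASSES:
            if profile[c]:
                sites.extend(rng.choice(pools[c], size=profile[c], replace=False))
        draws.append(
            EvidenceSet(
                condition_name=f"{ev.condition_name}::random{i}",
                sites=frozenset(sites),
                residue_class=ev.residue_class,
                n=len(sites),
            )
        )
    return RandomExperimentSet(draws=draws, class_profile=profile)


def _mw_exact_less(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided Mann-Whitney p (alternative: x stochastically smaller).

    Permutation enumeration over all ways to label the pooled values; valid
    with ties. Feasible for small samples only.
    """
    pooled = np.concatenate([x, y])
    nx = len(x)
    idx = range(len(pooled))

    def u_stat(xs_idx):
        xs = pooled[list(xs_idx)]
        ys = np.delete(pooled, list(xs_idx))
        # U = #{(i,j): x_i > y_j} + 0.5 #ties; small U supports "x smaller"
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(range(nx))
    count = 0
    total = 0
    for comb in combinations(idx, nx):
        total += 1
        if u_stat(comb) <= u_obs + 1e-12:
            count += 1
    return count / total


def mw_aggregate(real_pvals, random_pvals) -> tuple:
    """One-sided Mann-Whitney aggregation of ensemble p-values.

    Tests whether the real networks' enrichment p-values are stochastically
    smaller (more significant) than the pooled random ones. Returns
    ``(mw_p, score)`` with ``score = -log10(mw_p)``.

    Uses exact permutation enumeration when both sides have at most
    ``EXACT_MW_LIMIT`` values, otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(real_pvals, dtype=float).ravel()
    y = np.asarray(random_pvals, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both p-value collections must be non-empty")
    if x.size <= EXACT_MW_LIMIT and y.size <= EXACT_MW_LIMIT:
        p = _mw_exact_less(x, y)
    else:
        res = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        p = float(res.pvalue)
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return p, -math.log10(p)


def _random_enrichment_tensor(
    rand: RandomExperimentSet, index: _EnsembleIndex
) -> np.ndarray:
    """Hypergeometric p-values for every draw: shape (draws, networks, kinases)."""
    E = np.stack([index.evidence_vector(d.sites) for d in rand.draws])
    k_all = np.einsum("nks,ds->dnk", index.M, E.astype(np.int64))
    n = int(E[0].sum())
    return _sf_matrix(k_all, index.K[None, :, :], n, index.N)


def _pool(random_p: np.ndarray, pooling: str) -> np.ndarray:
    """Reduce the (draws, networks) random p-values of one kinase to the MW
    comparison group."""
    if pooling == "pooled":
        return random_p.ravel()
    return np.median(random_p, axis=1)


def estimate_fpr(
    real_mw_p: pd.Series,
    random_tensor: np.ndarray,
    kinases: list,
    n_decoys: int = N_DECOYS,
    pooling: str = "pooled",
    comparison: str = "le",
) -> pd.Series:
    """Empirical false-positive rates from decoy experiments.

    For each of ``n_decoys`` iterations, one random draw plays the role of
    the real experiment and is aggregated against the remaining draws; the
    FPR of a kinase is the proportion of decoy Mann-Whitney p-values at least
    as significant as the real one.
    """
    n_draws = random_tensor.shape[0]
    if n_decoys > n_draws - 1:
        raise ValueError(
            f"n_decoys={n_decoys} requires at least n_decoys+1={n_decoys + 1} "
            f"random draws, have {n_draws}"
        )
    counts = pd.Series(0, index=pd.Index(kinases), dtype=float)
    for d in range(n_decoys):
        rest = np.delete(random_tensor, d, axis=0)
        for ki, kinase in enumerate(kinases):
            decoy_p, _ = mw_aggregate(
                random_tensor[d, :, ki], _pool(rest[:, :, ki], pooling)
            )
            real = real_mw_p[kinase]
            hit = decoy_p <= real if comparison == "le" else decoy_p < real
            counts[kinase] += hit
    return counts / n_decoys


@dataclass
class ActivityProfile:
    """Per-kinase activity results for one condition.

    ``table`` columns: ``mw_p``, ``score`` (= -log10 mw_p), ``fpr``,
    ``median_hypergeom_p``, ``n_evidence``; indexed by kinase.
    """

    table: pd.DataFrame
    condition_name: str
    n: int
    N: int
    seed: int | None = None

    @property
    def kinases(self) -> list:
        return list(self.table.index)

    def write(self, path, sep="\t") -> None:
        out = self.table.copy()
        out.insert(0, "kinase", out.index)
        out.to_csv(path, sep=sep, index=False)


def run_kstar(
    ev: EvidenceSet,
    ens: NetworkEnsemble,
    proteome: Phosphoproteome,
    cfg: InferenceConfig = InferenceConfig(),
    fpr_kinases=None,
) -> ActivityProfile:
    """Full activity inference for one evidence set (the KSTAR procedure).

    Orchestrates enrichment, random-experiment generation, Mann-Whitney
    aggregation and decoy-based FPR estimation; deterministic given
    ``cfg.seed``. ``fpr_kinases`` optionally restricts the (expensive) decoy
    stage to a kinase subset, leaving other kinases' FPR as NaN.
    """
    index = _EnsembleIndex(ens, proteome, ev.residue_class)
    real = enrich(ev, ens, proteome, _index=index)
    rand = draw_random_experiments(ev, proteome, n_random=cfg.n_random, seed=cfg.seed)
    tensor = _random_enrichment_tensor(rand, index)

    kinases = index.kinases
    mw_p = {}
    score = {}
    for ki, kinase in enumerate(kinases):
        p, s = mw_aggregate(
            real.pvals.loc[kinase].to_numpy(), _pool(tensor[:, :, ki], cfg.random_pooling)
        )
        mw_p[kinase] = p
        score[kinase] = s
    mw_series = pd.Series(mw_p)

    targets = list(fpr_kinases) if fpr_kinases is not None else kinases
    target_idx = [kinases.index(k) for k in targets]
    fpr_sub = estimate_fpr(
        mw_series,
        tensor[:, :, target_idx],
        targets,
        n_decoys=cfg.n_decoys,
        pooling=cfg.random_pooling,
        comparison=cfg.fpr_comparison,
    )
    fpr = pd.Series(np.nan, index=pd.Index(kinases))
    fpr[fpr_sub.index] = fpr_sub

    table = pd.DataFrame(
        {
            "mw_p": mw_series,
            "score": pd.Series(score),
            "fpr": fpr,
            "median_hypergeom_p": real.pvals.median(axis=1),
            "n_evidence": real.n,
        },
        index=pd.Index(kinases, name="kinase"),
    )
    return ActivityProfile(
        table=table, condition_name=ev.condition_name, n=real.n, N=real.N, seed=cfg.seed
    )


_CALL_RULES = {
    "fpr05": lambda t: t["fpr"] <= 0.05,
    "fpr10": lambda t: t["fpr"] <= 0.1,
    "score3": lambda t: t["score"] > 3,
}


def binary_call(profile: ActivityProfile, rule: str) -> set:
    """Kinases called active under a cutoff rule.

    ``rule`` is one of ``fpr05`` (FPR <= 0.05), ``fpr10`` (FPR <= 0.1) or
    ``score3`` (score > 3).
    """
    if rule not in _CALL_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(_CALL_RULES)}")
    mask = _CALL_RULES[rule](profile.table)
    return set(profile.table.index[mask.fillna(False)])
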
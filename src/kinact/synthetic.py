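"""Synthetic fixture generators: proteomes, networks, annotations, experiments.

Everything downstream of raw predictions is testable without external data:
this module fabricates reference phosphoproteomes with a controllable
study-bias distribution, dense weighted kinase-substrate graphs with
per-kinase preferred substrate cores, annotation sets, and experiments with
an optional *planted* kinase signal (a chosen fraction of evidence drawn from
one kinase's substrates).

The default study-bias distribution is heavy-tailed — most sites appear in no
annotation compendium and very few in all five — emulating the strong
annotation skew of real phosphoproteomes that the class-matched resampling is
designed to control. Generated graphs give every kinase a high-weight "core"
of preferred substrates plus a low-weight background so that kinases have
distinguishable substrate neighborhoods while still exercising the substrate
cap; real prediction graphs are of course less cleanly separable.

All generators are deterministic under their seed, and feasibility of the
default pruning quotas is checked at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparators import AnnotationSet, QuantExperiment
from .networks import (
    NetworkEnsemble,
    PruneConfig,
    WeightedNetwork,
    compute_bias_quota,
)
from .reference import EvidenceSet, Phosphoproteome

__all__ = [
    "SynthSpec",
    "gen_phosphoproteome",
    "gen_weighted_network",
    "gen_experiment",
    "gen_quant_experiment",
    "gen_annotations",
]

#: Heavy-tailed default over compendia counts 0..5.
DEFAULT_BIAS_DISTRIBUTION = (0.55, 0.20, 0.10, 0.07, 0.05, 0.03)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic system.

    ``weight_core``/``weight_background`` are the Beta-ish weight levels of a
    kinase's preferred substrates vs everything else; ``core_size_factor``
    times the per-kinase substrate quota gives the core size;
    ``candidate_fraction`` is the fraction of all sites each kinase is
    connected to in the dense graph.
    """

    n_sites: int = 5000
    residue_class: str = "Y"
    bias_distribution: tuple = DEFAULT_BIAS_DISTRIBUTION
    n_kinases: int = 20
    substrates_per_kinase: int = 500
    core_size_factor: float = 1.5
    candidate_fraction: float = 0.6
    weight_core: float = 0.9
    weight_background: float = 0.05
    weight_jitter: float = 0.05
    planted: tuple | None = None  # (kinase, enrichment_fraction)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.residue_class not in ("Y", "ST"):
            raise ValueError("residue_class must be 'Y' or 'ST'")
        if abs(sum(self.bias_distribution) - 1.0) > 1e-9:
            raise ValueError("bias_distribution must sum to 1")
        if len(self.bias_distribution) != 6:
            raise ValueError("bias_distribution must have 6 probabilities (counts 0..5)")
        if self.planted is not None and not 0 <= self.planted[1] <= 1:
            raise ValueError("enrichment_fraction must be in [0, 1]")


def _site_rows(spec: SynthSpec, rng: np.random.Generator) -> pd.DataFrame:
    residues = (
        np.full(spec.n_sites, "Y")
        if spec.residue_class == "Y"
        else rng.choice(["S", "T"], size=spec.n_sites)
    )
    counts = rng.choice(6, size=spec.n_sites, p=np.asarray(spec.bias_distribution))
    return pd.DataFrame(
        {
            "accession": [f"SYN{i:05d}" for i in range(spec.n_sites)],
            "residue": residues,
            "position": rng.integers(1, 2000, size=spec.n_sites),
            "compendia_count": counts,
        }
    )


def gen_phosphoproteome(spec: SynthSpec) -> Phosphoproteome:
    """Generate a reference phosphoproteome with the requested bias profile."""
    rng = np.random.default_rng(spec.seed)
    return Phosphoproteome(_site_rows(spec, rng))


def kinase_names(spec: SynthSpec) -> list:
    return [f"KIN{i:02d}" for i in range(spec.n_kinases)]


def gen_weighted_network(spec: SynthSpec, proteome: Phosphoproteome) -> WeightedNetwork:
    """Generate a dense weighted graph feasible under the default prune quotas.

    Each kinase receives edges to ``candidate_fraction`` of all sites; its
    (disjointly sampled per kinase where possible) core sites get weights
    near ``weight_core``, the rest near ``weight_background``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    sites = np.asarray(sorted(proteome.background(spec.residue_class)))
    n_candidates = int(round(spec.candidate_fraction * len(sites)))
    core_size = int(round(spec.core_size_factor * spec.substrates_per_kinase))
    if n_candidates < spec.substrates_per_kinase:
        raise ValueError(
            f"candidate_fraction too small: {n_candidates} candidates per kinase "
            f"< substrates_per_kinase={spec.substrates_per_kinase}"
        )
    # check bin-level feasibility of the default quota against expected
    # per-bin candidate availability
    quota = compute_bias_quota(proteome, spec.substrates_per_kinase, spec.residue_class)
    counts = proteome.compendia_counts(spec.residue_class)
    for b, q in quota.items():
        avail = counts[b] * spec.candidate_fraction
        if q > avail:
            raise ValueError(
                f"bias bin {b}: quota {q} exceeds expected candidate availability "
                f"{avail:.0f}; increase candidate_fraction or n_sites"
            )

    core_size = min(core_size, n_candidates)
    # assign cores round-robin over a shuffled site order so cores overlap
    # as little as the universe allows
    shuffled = rng.permutation(sites)
    rows = []
    for ki, kinase in enumerate(kinase_names(spec)):
        start = (ki * core_size) % len(sites)
        core = set(np.take(shuffled, np.arange(start, start + core_size), mode="wrap"))
        candidates = set(rng.choice(sites, size=n_candidates, replace=False)) | core
        for s in sorted(candidates):
            base = spec.weight_core if s in core else spec.weight_background
            w = np.clip(base + rng.uniform(-spec.weight_jitter, spec.weight_jitter), 1e-6, 1.0)
            rows.append((kinase, s, w))
    return WeightedNetwork(
        pd.DataFrame(rows, columns=["kinase", "site", "weight"]),
        residue_class=spec.residue_class,
    )


def _planted_pool(spec: SynthSpec, network) -> frozenset:
    """Substrate pool of the planted kinase in a weighted network or ensemble."""
    kinase = spec.planted[0]
    if isinstance(network, NetworkEnsemble):
        if kinase not in network.kinases:
            raise KeyError(f"planted kinase {kinase!r} not in the ensemble")
        pool: set = set()
        for n in network.networks:
            pool |= n.membership[kinase]
        return frozenset(pool)
    if isinstance(network, WeightedNetwork):
        edges = network.edges
        sub = edges[edges["kinase"] == kinase]
        if sub.empty:
            raise KeyError(f"planted kinase {kinase!r} not in the network")
        # preferred (top-weight) substrates carry the signal
        top = sub.nlargest(spec.substrates_per_kinase, "weight")
        return frozenset(top["site"])
    raise TypeError(f"unsupported network type {type(network).__name__}")


def gen_experiment(
    spec: SynthSpec,
    proteome: Phosphoproteome,
    network=None,
    size: int = 100,
    name: str | None = None,
    seed: int | None = None,
) -> EvidenceSet:
    """Generate an evidence set, optionally with a planted kinase signal.

    A fraction ``enrichment_fraction`` of the ``size`` sites is drawn from
    the planted kinase's substrate pool (the high-weight edges of a weighted
    network, or the union membership in an ensemble), the remainder uniformly
    from the rest of the background.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    background = np.asarray(sorted(proteome.background(spec.residue_class)))
    if size > len(background):
        raise ValueError(f"requested {size} sites but background has {len(background)}")

    member_sites: list = []
    if spec.planted is not None and spec.planted[1] > 0:
        if network is None:
            raise ValueError("a network or ensemble is required for a planted signal")
        pool = np.asarray(sorted(_planted_pool(spec, network) & set(background)))
        n_member = int(round(spec.planted[1] * size))
        if n_member > len(pool):
            raise ValueError(
                f"planted kinase pool has {len(pool)} sites < requested {n_member}"
            )
        member_sites = list(rng.choice(pool, size=n_member, replace=False))
    rest_pool = np.asarray(sorted(set(background) - set(member_sites)))
    n_rest = size - len(member_sites)
    rest = list(rng.choice(rest_pool, size=n_rest, replace=False))
    sites = frozenset(member_sites) | frozenset(rest)
    return EvidenceSet.from_sites(
        name or ("planted" if member_sites else "null"),
        sites,
        spec.residue_class,
        proteome,
    )


def gen_quant_experiment(
    spec: SynthSpec,
    ev: EvidenceSet,
    member_sites=None,
    shift: float = 1.0,
    sigma: float = 1.0,
    seed: int | None = None,
) -> QuantExperiment:
    """Attach quantitative columns to an evidence set for comparator tests.

    log2 fold changes are Gaussian noise (sd ``sigma``) with a planted mean
    ``shift`` on ``member_sites``; intensities are the exponentiated values.
    """
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    sites = sorted(ev.sites)
    member_sites = set(member_sites or ())
    fc = rng.normal(0.0, sigma, size=len(sites))
    fc += np.asarray([shift if s in member_sites else 0.0 for s in sites])
    log2fc = pd.Series(fc, index=sites)
    intensity = pd.Series(np.exp2(fc - fc.min()), index=sites)
    return QuantExperiment(log2fc=log2fc, intensity=intensity)


def gen_annotations(
    spec: SynthSpec,
    net: WeightedNetwork,
    per_kinase: int = 25,
    seed: int | None = None,
) -> AnnotationSet:
    """Sample a sparse annotation set (top-weight edges) from a dense graph."""
    rng = np.random.default_rng(spec.seed + 4 if seed is None else seed)
    subs = {}
    for kinase, sub in net.edges.groupby("kinase"):
        top = sub.nlargest(min(per_kinase * 2, len(sub)), "weight")
        chosen = rng.choice(
            top["site"].to_numpy(), size=min(per_kinase, len(top)), replace=False
        )
        subs[str(kinase)] = set(chosen)
    return AnnotationSet(subs)
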
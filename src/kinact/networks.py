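"""Weighted kinase-substrate prediction graphs and heuristic pruning.

Kinase-substrate prediction algorithms emit a dense weighted bipartite graph:
every kinase scored against essentially every phosphosite. Used directly (or
naively thresholded), such graphs suffer from huge kinase-kinase overlap and
from the centrality of well-studied substrates. The pruning procedure here
converts the dense graph into an ensemble of sparse *binary* networks, each an
alternate plausible set of kinase-substrate relationships, by probabilistic
edge selection proportional to edge weight under three constraints:

1. every kinase finishes with exactly ``substrates_per_kinase`` substrates;
2. no substrate is connected to more than ``max_kinases_per_substrate``
   kinases (no hub substrates);
3. each kinase's substrates match a fixed study-bias composition (the
   ``bias_quota``), mirroring the bias distribution of the whole
   phosphoproteome, so well-studied sites cannot dominate any kinase.

Defaults follow the published procedure: 2000 substrates per tyrosine kinase
(cap 10 kinases/substrate) and 2500 per serine/threonine kinase (cap 20),
with 50 networks per ensemble. Pruning uses exact compendia counts (0..5) as
the bias bins; the coarser low/medium/high classes are used only for random
background draws.

Sequential weighted sampling without replacement is realised through the
exponential-race construction: each candidate edge receives an independent
key ``Exp(1)/weight`` and edges are consumed in ascending key order. At every
draw, the minimum-key edge among the currently eligible candidates is selected
with probability proportional to its weight, which is exactly the sequential
weighted draw-with-removal scheme, but needs a single sort per kinase/bin.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import (
    BIAS_CLASSES,
    EvidenceSet,
    Phosphoproteome,
    SiteID,
    canonicalize_site,
    study_bias_class,
    _read_delimited,
)

__all__ = [
    "WeightedNetwork",
    "PruneConfig",
    "PrunedNetwork",
    "NetworkEnsemble",
    "load_weighted_network",
    "compute_bias_quota",
    "prune_network",
    "build_ensemble",
    "kinase_overlap",
    "site_coverage",
    "InfeasiblePruneError",
]

#: Published default pruning parameters per residue class.
DEFAULT_SUBSTRATES_PER_KINASE = {"Y": 2000, "ST": 2500}
DEFAULT_MAX_KINASES_PER_SUBSTRATE = {"Y": 10, "ST": 20}
DEFAULT_N_NETWORKS = 50


class NetworkParseError(ValueError):
    pass


class InfeasiblePruneError(RuntimeError):
    """A kinase cannot satisfy its substrate quota from available candidates."""


class WeightedNetwork:
    """A dense weighted kinase -> phosphosite prediction graph.

    Edge weights must lie in (0, 1]; duplicate (kinase, site) pairs are
    rejected; all sites must share one residue class.
    """

    def __init__(self, edges: pd.DataFrame, residue_class: str | None = None):
        required = {"kinase", "site", "weight"}
        missing = required - set(edges.columns)
        if missing:
            raise NetworkParseError(f"edge table missing columns: {sorted(missing)}")
        edges = edges[["kinase", "site", "weight"]].copy()
        w = pd.to_numeric(edges["weight"], errors="coerce")
        if w.isna().any():
            bad = int(np.argmax(w.isna().to_numpy()))
            raise NetworkParseError(f"non-numeric weight at edge row {bad}")
        if ((w <= 0) | (w > 1)).any():
            bad = int(np.argmax(((w <= 0) | (w > 1)).to_numpy()))
            raise NetworkParseError(
                f"edge weight outside (0, 1] at row {bad}: {w.iloc[bad]}"
            )
        edges["weight"] = w.astype(float)
        if edges.duplicated(["kinase", "site"]).any():
            dup = edges[edges.duplicated(["kinase", "site"])].iloc[0]
            raise NetworkParseError(
                f"duplicate edge ({dup['kinase']}, {dup['site']})"
            )
        classes = {SiteID.from_key(k).residue_class for k in edges["site"].unique()}
        if len(classes) > 1:
            raise NetworkParseError("network mixes Y and ST sites")
        inferred = classes.pop() if classes else None
        if residue_class is None:
            residue_class = inferred
        elif inferred is not None and inferred != residue_class:
            raise NetworkParseError(
                f"sites are {inferred} but residue_class={residue_class!r}"
            )
        self.edges = edges.reset_index(drop=True)
        self.residue_class = residue_class

    @property
    def kinases(self) -> list:
        return sorted(self.edges["kinase"].unique())

    @property
    def sites(self) -> frozenset:
        return frozenset(self.edges["site"])

    def __len__(self) -> int:
        return len(self.edges)


def load_weighted_network(path, sep=None) -> WeightedNetwork:
    """Load a weighted network from delimited text.

    Accepts either columns (kinase, site, weight) with canonical site keys or
    columns (kinase, accession, residue, position, weight).
    """
    df = _read_delimited(path, sep)
    if {"accession", "residue", "position"} <= set(df.columns):
        sites = []
        for i, (acc, res, pos) in enumerate(
            zip(df["accession"], df["residue"], df["position"])
        ):
            try:
                sites.append(canonicalize_site(acc, res, int(pos)).key)
            except (ValueError, TypeError) as exc:
                raise NetworkParseError(f"line {i + 2}: {exc}") from exc
        df = pd.DataFrame(
            {"kinase": df["kinase"], "site": sites, "weight": df["weight"]}
        )
    elif not {"kinase", "site", "weight"} <= set(df.columns):
        raise NetworkParseError(
            "expected columns kinase/site/weight or kinase/accession/residue/position/weight"
        )
    return WeightedNetwork(df)


def compute_bias_quota(
    proteome: Phosphoproteome,
    substrates_per_kinase: int,
    residue_class: str,
    bins: str = "compendia",
) -> dict:
    """Apportion a kinase's substrate limit across study-bias bins.

    Quotas are proportional to each bin's share of the matching-class
    phosphoproteome, integerized by largest-remainder rounding so they sum
    exactly to ``substrates_per_kinase``. ``bins="compendia"`` uses exact
    compendia counts 0..5 (the default for pruning); ``bins="class"`` uses the
    low/medium/high grouping.
    """
    if substrates_per_kinase <= 0:
        raise ValueError("substrates_per_kinase must be positive")
    if bins == "compendia":
        counts = proteome.compendia_counts(residue_class)
    elif bins == "class":
        counts = proteome.class_counts(residue_class)
    else:
        raise ValueError(f"bins must be 'compendia' or 'class', got {bins!r}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"phosphoproteome has no {residue_class} sites")
    exact = {b: substrates_per_kinase * c / total for b, c in counts.items()}
    quota = {b: int(np.floor(v)) for b, v in exact.items()}
    leftover = substrates_per_kinase - sum(quota.values())
    # largest remainder; ties broken by bin order (ascending study bias);
    # bins with no proteome sites never receive a rounding allocation
    order = sorted(
        (b for b in counts if counts[b] > 0),
        key=lambda b: (-(exact[b] - quota[b]), _bin_sort_key(b)),
    )
    for b in order[:leftover]:
        quota[b] += 1
    return quota


def _bin_sort_key(b):
    if isinstance(b, str):
        return BIAS_CLASSES.index(b)
    return int(b)


@dataclass(frozen=True)
class PruneConfig:
    """Parameters controlling pruning of one weighted network."""

    substrates_per_kinase: int
    max_kinases_per_substrate: int
    bias_quota: dict
    n_networks: int = DEFAULT_N_NETWORKS
    seed: int = 0

    def __post_init__(self):
        if self.substrates_per_kinase <= 0:
            raise ValueError("substrates_per_kinase must be positive")
        if self.max_kinases_per_substrate <= 0:
            raise ValueError("max_kinases_per_substrate must be positive")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if any(v < 0 for v in self.bias_quota.values()):
            raise ValueError("bias_quota counts must be non-negative")
        if sum(self.bias_quota.values()) != self.substrates_per_kinase:
            raise ValueError(
                "bias_quota must sum to substrates_per_kinase "
                f"({sum(self.bias_quota.values())} != {self.substrates_per_kinase})"
            )

    @classmethod
    def default_for(
        cls,
        residue_class: str,
        proteome: Phosphoproteome,
        substrates_per_kinase: int | None = None,
        max_kinases_per_substrate: int | None = None,
        n_networks: int = DEFAULT_N_NETWORKS,
        seed: int = 0,
        bins: str = "compendia",
    ) -> "PruneConfig":
        spk = substrates_per_kinase or DEFAULT_SUBSTRATES_PER_KINASE[residue_class]
        cap = max_kinases_per_substrate or DEFAULT_MAX_KINASES_PER_SUBSTRATE[residue_class]
        quota = compute_bias_quota(proteome, spk, residue_class, bins=bins)
        return cls(spk, cap, quota, n_networks=n_networks, seed=seed)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "substrates_per_kinase": self.substrates_per_kinase,
                "max_kinases_per_substrate": self.max_kinases_per_substrate,
                "bias_quota": {str(k): v for k, v in sorted(self.bias_quota.items(), key=lambda kv: str(kv[0]))},
                "n_networks": self.n_networks,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PrunedNetwork:
    """One binary kinase -> substrate network satisfying the prune constraints."""

    membership: dict  # kinase -> frozenset of site keys
    bin_counts: dict  # kinase -> {bin: selected count} (after any fallback)
    provenance: tuple  # (seed, config hash)
    fallback_log: list = field(default_factory=list)

    @property
    def kinases(self) -> list:
        return sorted(self.membership)

    @property
    def sites(self) -> frozenset:
        out = set()
        for m in self.membership.values():
            out |= m
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kinase in self.kinases:
            for key in sorted(self.membership[kinase]):
                sid = SiteID.from_key(key)
                rows.append((kinase, sid.accession, sid.residue, sid.position))
        return pd.DataFrame(rows, columns=["kinase", "accession", "residue", "position"])

    def write(self, path, sep="\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read(cls, path, sep="\t") -> "PrunedNetwork":
        df = pd.read_csv(path, sep=sep)
        membership = {}
        for kinase, sub in df.groupby("kinase"):
            membership[str(kinase)] = frozenset(
                canonicalize_site(a, r, int(p)).key
                for a, r, p in zip(sub["accession"], sub["residue"], sub["position"])
            )
        return cls(membership, bin_counts={}, provenance=(None, None))


def _bin_of(proteome: Phosphoproteome, key: str, quota_bins) -> object:
    count = proteome.compendia_count(key)
    if all(isinstance(b, str) for b in quota_bins):
        return study_bias_class(count)
    return count


def prune_network(
    net: WeightedNetwork,
    proteome: Phosphoproteome,
    cfg: PruneConfig,
    seed: int,
) -> PrunedNetwork:
    """Prune one binary network from a dense weighted graph.

    Kinases are visited round-robin, one edge per visit, each visit filling
    the study-bias bin with the largest remaining quota (ties broken toward
    less-studied bins). Within a (kinase, bin), candidate edges are consumed
    in the exponential-race order, i.e. sequential weighted sampling without
    replacement; edges to substrates that have reached the global substrate
    cap are skipped. If a bin runs out of candidates, its deficit is borrowed
    by the nearest bin (preferring less-studied) and logged; a kinase whose
    total candidate pool cannot cover its remaining quota raises
    :class:`InfeasiblePruneError`.
    """
    rng = np.random.default_rng(seed)
    quota_bins = sorted(cfg.bias_quota, key=_bin_sort_key)
    cap = cfg.max_kinases_per_substrate

    edges = net.edges
    site_keys = pd.Index(sorted(net.sites))
    site_pos = {k: i for i, k in enumerate(site_keys)}
    missing = [k for k in site_keys if k not in proteome]
    if missing:
        raise ValueError(
            f"network sites absent from phosphoproteome: {missing[:5]}"
        )
    site_bin = [_bin_of(proteome, k, quota_bins) for k in site_keys]

    kinases = net.kinases
    # per (kinase, bin): candidate site indices in exponential-race order
    orders: dict = {}
    pointers: dict = {}
    for kinase in kinases:
        sub = edges[edges["kinase"] == kinase]
        idx = np.array([site_pos[s] for s in sub["site"]], dtype=np.int64)
        w = sub["weight"].to_numpy()
        if len(idx) < cfg.substrates_per_kinase:
            raise InfeasiblePruneError(
                f"kinase {kinase}: {len(idx)} candidate edges < "
                f"substrates_per_kinase={cfg.substrates_per_kinase}"
            )
        keys = rng.exponential(1.0, size=len(idx)) / w
        order = np.argsort(keys, kind="stable")
        bins_arr = np.array([site_bin[i] for i in idx], dtype=object)
        for b in quota_bins:
            mask = bins_arr[order] == b
            orders[kinase, b] = idx[order[mask]]
            pointers[kinase, b] = 0

    remaining = {k: dict(cfg.bias_quota) for k in kinases}
    membership = {k: [] for k in kinases}
    bin_counts = {k: {b: 0 for b in quota_bins} for k in kinases}
    degree = np.zeros(len(site_keys), dtype=np.int64)
    fallback_log: list = []
    bin_order_index = {b: i for i, b in enumerate(quota_bins)}

    def _next_eligible(kinase, b):
        """Advance the (kinase, bin) pointer past capped sites; None if exhausted."""
        arr = orders[kinase, b]
        p = pointers[kinase, b]
        while p < len(arr) and degree[arr[p]] >= cap:
            p += 1
        pointers[kinase, b] = p
        return arr[p] if p < len(arr) else None

    active = [k for k in kinases if cfg.substrates_per_kinase > 0]
    while active:
        still_active = []
        for kinase in active:
            rem = remaining[kinase]
            # bin with largest remaining quota; ties toward less-studied bins
            open_bins = [b for b in quota_bins if rem[b] > 0]
            if not open_bins:
                continue
            b = max(open_bins, key=lambda x: (rem[x], -bin_order_index[x]))
            site = _next_eligible(kinase, b)
            while site is None:
                # bin exhausted: borrow the deficit into the nearest bin
                # (preferring less-studied) that still has candidates
                targets = [
                    t
                    for t in quota_bins
                    if t != b and pointers[kinase, t] < len(orders[kinase, t])
                ]
                targets = [t for t in targets if _next_eligible(kinase, t) is not None]
                if not targets:
                    raise InfeasiblePruneError(
                        f"kinase {kinase}: bin {b!r} exhausted and no other bin "
                        f"has eligible candidates ({rem[b]} substrates short)"
                    )
                t = min(
                    targets,
                    key=lambda x: (
                        abs(bin_order_index[x] - bin_order_index[b]),
                        bin_order_index[x],
                    ),
                )
                fallback_log.append(
                    f"kinase {kinase}: bin {b!r} exhausted with {rem[b]} "
                    f"remaining; borrowed by bin {t!r}"
                )
                rem[t] += rem[b]
                rem[b] = 0
                b = t
                site = _next_eligible(kinase, b)
            membership[kinase].append(site)
            degree[site] += 1
            pointers[kinase, b] += 1
            rem[b] -= 1
            bin_counts[kinase][b] += 1
            if any(v > 0 for v in rem.values()):
                still_active.append(kinase)
        active = still_active

    return PrunedNetwork(
        membership={
            k: frozenset(site_keys[i] for i in v) for k, v in membership.items()
        },
        bin_counts=bin_counts,
        provenance=(seed, cfg.hash()),
        fallback_log=fallback_log,
    )


@dataclass
class NetworkEnsemble:
    """An ordered collection of pruned binary networks over one kinase set."""

    networks: list
    config: PruneConfig | None = None

    def __post_init__(self):
        if not self.networks:
            raise ValueError("ensemble must contain at least one network")
        ref = set(self.networks[0].membership)
        for i, n in enumerate(self.networks[1:], start=1):
            if set(n.membership) != ref:
                raise ValueError(f"network {i} has a different kinase set")

    @property
    def kinases(self) -> list:
        return self.networks[0].kinases

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def union_sites(self) -> frozenset:
        out = set()
        for n in self.networks:
            out |= n.sites
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.networks)

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        manifest = {
            "n_networks": self.n_networks,
            "members": [],
        }
        if self.config is not None:
            manifest["config_hash"] = self.config.hash()
            manifest["base_seed"] = self.config.seed
        for i, n in enumerate(self.networks):
            fname = f"network_{i:03d}.tsv"
            n.write(os.path.join(out_dir, fname))
            manifest["members"].append(
                {"file": fname, "seed": n.provenance[0], "config_hash": n.provenance[1]}
            )
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def read(cls, out_dir) -> "NetworkEnsemble":
        with open(os.path.join(out_dir, "manifest.json")) as fh:
            manifest = json.load(fh)
        networks = []
        for member in manifest["members"]:
            n = PrunedNetwork.read(os.path.join(out_dir, member["file"]))
            n.provenance = (member.get("seed"), member.get("config_hash"))
            networks.append(n)
        return cls(networks)


def build_ensemble(
    net: WeightedNetwork, proteome: Phosphoproteome, cfg: PruneConfig
) -> NetworkEnsemble:
    """Prune ``cfg.n_networks`` networks with seeds ``seed, seed+1, ...``.

    Re-running with the same base seed reproduces the ensemble exactly.
    """
    networks = [
        prune_network(net, proteome, cfg, seed=cfg.seed + i)
        for i in range(cfg.n_networks)
    ]
    return NetworkEnsemble(networks, config=cfg)


def kinase_overlap(net: PrunedNetwork, k1: str, k2: str, restrict_to=None) -> float:
    """Jaccard overlap of two kinases' substrate sets in one pruned network."""
    for k in (k1, k2):
        if k not in net.membership:
            raise KeyError(f"unknown kinase {k!r}")
    a, b = set(net.membership[k1]), set(net.membership[k2])
    if restrict_to is not None:
        restrict_to = set(restrict_to)
        a &= restrict_to
        b &= restrict_to
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def site_coverage(ens: NetworkEnsemble, ev: EvidenceSet) -> float:
    """Fraction of evidence sites present anywhere in the ensemble."""
    if not ev.sites:
        raise ValueError("evidence set is empty")
    return len(ev.sites & ens.union_sites) / len(ev.sites)
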
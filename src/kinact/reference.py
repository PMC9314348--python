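"""Reference phosphoproteome, site identity, experiment mapping and binary evidence.

The atomic unit of evidence throughout this package is the *phosphosite*: a
phosphorylatable tyrosine (Y), serine (S) or threonine (T) residue at a
1-based position on a protein accession. Sites are keyed by the canonical
string form ``"ACCESSION_R###"`` (e.g. ``"P00533_Y1068"``), which is bijective
with the (accession, residue, position) triple.

Tyrosine (Y) and serine/threonine (ST) sites are treated as fully independent
universes downstream: networks, backgrounds and random draws never mix the two
residue classes.

Study bias — how well-studied a site is — is quantified as the number of
annotation compendia (0-5) the site appears in, and is grouped into three
classes (low: 0, medium: 1-2, high: 3-5) for background resampling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteID",
    "canonicalize_site",
    "study_bias_class",
    "Phosphoproteome",
    "MappedExperiment",
    "EvidenceSet",
    "map_experiment",
    "binarize_evidence",
    "LOW_EVIDENCE_Y",
    "LOW_EVIDENCE_ST",
]

#: Typical minimum evidence sizes below which a warning is emitted.
LOW_EVIDENCE_Y = 50
LOW_EVIDENCE_ST = 1000

_VALID_RESIDUES = frozenset("YST")
_SITE_KEY_RE = re.compile(r"^(?P<acc>.+)_(?P<res>[YST])(?P<pos>[0-9]+)$")
_SITE_DESC_RE = re.compile(r"^(?P<res>[YSTyst])(?P<pos>[0-9]+)$")


class SiteValidationError(ValueError):
    """A site triple failed validation; the message names the offending field."""


@dataclass(frozen=True, order=True)
class SiteID:
    """A phosphosite: protein accession, residue (Y/S/T), 1-based position."""

    accession: str
    residue: str
    position: int

    @property
    def key(self) -> str:
        """Canonical string form, e.g. ``"P00533_Y1068"``."""
        return f"{self.accession}_{self.residue}{self.position}"

    @property
    def residue_class(self) -> str:
        """``"Y"`` for tyrosine sites, ``"ST"`` for serine/threonine sites."""
        return "Y" if self.residue == "Y" else "ST"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key

    @classmethod
    def from_key(cls, key: str) -> "SiteID":
        """Parse a canonical ``"ACCESSION_R###"`` string back into a SiteID."""
        m = _SITE_KEY_RE.match(key)
        if m is None:
            raise SiteValidationError(f"not a canonical site key: {key!r}")
        return cls(m.group("acc"), m.group("res"), int(m.group("pos")))


def canonicalize_site(accession: str, residue: str, position: int) -> SiteID:
    """Validate and normalize a site triple into a :class:`SiteID`.

    Residues are case-folded to upper case; positions must be >= 1.
    """
    if not accession:
        raise SiteValidationError("accession: must be a non-empty string")
    residue = str(residue).upper()
    if residue not in _VALID_RESIDUES:
        raise SiteValidationError(f"residue: {residue!r} not one of Y, S, T")
    position = int(position)
    if position < 1:
        raise SiteValidationError(f"position: {position} must be >= 1")
    return SiteID(str(accession), residue, position)


def study_bias_class(compendia_count: int) -> str:
    """Map a compendia count (0-5) to its study-bias class.

    0 -> ``"low"``; 1-2 -> ``"medium"``; 3-5 -> ``"high"``.
    """
    c = int(compendia_count)
    if not 0 <= c <= 5:
        raise SiteValidationError(f"compendia_count: {c} outside [0, 5]")
    if c == 0:
        return "low"
    if c <= 2:
        return "medium"
    return "high"


BIAS_CLASSES = ("low", "medium", "high")


class Phosphoproteome:
    """The reference phosphoproteome: the background universe of sites.

    Holds, per site, the compendia count (study bias, 0-5) and the residue
    class, and provides N — the background size per residue class — for the
    hypergeometric test.

    Parameters
    ----------
    table:
        DataFrame with columns ``accession``, ``residue``, ``position``,
        ``compendia_count``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"accession", "residue", "position", "compendia_count"}
        missing = required - set(table.columns)
        if missing:
            raise SchemaError(f"phosphoproteome missing columns: {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("phosphoproteome is empty")
        keys = []
        classes = []
        for acc, res, pos in zip(
            table["accession"], table["residue"], table["position"]
        ):
            sid = canonicalize_site(acc, res, pos)
            keys.append(sid.key)
            classes.append(sid.residue_class)
        df = pd.DataFrame(
            {
                "accession": table["accession"].to_numpy(),
                "residue": [k.rsplit("_", 1)[1][0] for k in keys],
                "position": table["position"].astype(int).to_numpy(),
                "compendia_count": table["compendia_count"].astype(int).to_numpy(),
                "residue_class": classes,
            },
            index=pd.Index(keys, name="site"),
        )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate phosphoproteome sites: {dups[:5]}")
        bad = ~df["compendia_count"].between(0, 5)
        if bad.any():
            raise SiteValidationError(
                f"compendia_count outside [0,5] for {df.index[bad].tolist()[:5]}"
            )
        df["bias_class"] = [study_bias_class(c) for c in df["compendia_count"]]
        self._df = df

    # -- basic accessors ---------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._df

    @property
    def sites(self) -> frozenset:
        return frozenset(self._df.index)

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, key: str) -> bool:
        return key in self._df.index

    def compendia_count(self, key: str) -> int:
        return int(self._df.at[key, "compendia_count"])

    def bias_class(self, key: str) -> str:
        return str(self._df.at[key, "bias_class"])

    def background(self, residue_class: str) -> pd.Index:
        """All site keys of the given residue class (``"Y"`` or ``"ST"``)."""
        if residue_class not in ("Y", "ST"):
            raise ValueError(f"residue_class must be 'Y' or 'ST', got {residue_class!r}")
        return self._df.index[self._df["residue_class"] == residue_class]

    def background_size(self, residue_class: str) -> int:
        """N of the hypergeometric test for one residue class."""
        return int((self._df["residue_class"] == residue_class).sum())

    def class_counts(self, residue_class: str) -> dict:
        """Per study-bias class site counts within one residue class."""
        sub = self._df[self._df["residue_class"] == residue_class]
        vc = sub["bias_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in BIAS_CLASSES}

    def compendia_counts(self, residue_class: str) -> dict:
        """Per exact compendia-count (0..5) site counts within one residue class."""
        sub = self._df[self._df["residue_class"] == residue_class]
        vc = sub["compendia_count"].value_counts()
        return {c: int(vc.get(c, 0)) for c in range(6)}

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_file(cls, path, sep=None) -> "Phosphoproteome":
        return cls(_read_delimited(path, sep))

    def to_file(self, path, sep="\t") -> None:
        self._df[["accession", "residue", "position", "compendia_count"]].to_csv(
            path, sep=sep, index=False
        )


class SchemaError(ValueError):
    """Input table lacks a required column."""


@dataclass
class MappedExperiment:
    """An experiment table mapped onto the reference phosphoproteome.

    ``rows`` retains only rows whose site exists in the reference; every input
    row (mapped or excluded) appears once in ``mapping_log``.
    """

    rows: pd.DataFrame  # indexed by site key; condition columns preserved
    mapping_log: pd.DataFrame  # columns: row, outcome, message

    @property
    def sites(self) -> frozenset:
        return frozenset(self.rows.index)

    def n_mapped(self) -> int:
        return int((self.mapping_log["outcome"] == "mapped").sum())

    def n_excluded(self) -> int:
        return int((self.mapping_log["outcome"] == "excluded").sum())

    def write_log(self, path, sep="\t") -> None:
        self.mapping_log.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class EvidenceSet:
    """The binary set of sites treated as observed in one condition.

    ``n`` is the number of evidence sites that exist in the matching-class
    background — the *n* of the hypergeometric test.
    """

    condition_name: str
    sites: frozenset
    residue_class: str
    n: int

    def __post_init__(self):
        if self.residue_class not in ("Y", "ST"):
            raise ValueError(f"residue_class must be 'Y' or 'ST', got {self.residue_class!r}")
        if self.n > len(self.sites):
            raise ValueError("n cannot exceed the number of evidence sites")

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_sites(cls, name, sites, residue_class, proteome: Phosphoproteome):
        sites = frozenset(sites)
        background = set(proteome.background(residue_class))
        return cls(name, sites, residue_class, len(sites & background))


def _parse_site_descriptor(desc: str):
    m = _SITE_DESC_RE.match(str(desc).strip())
    if m is None:
        return None
    return m.group("res").upper(), int(m.group("pos"))


def _read_delimited(path, sep=None) -> pd.DataFrame:
    """Read a tab- or comma-delimited text table, sniffing the separator."""
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def map_experiment(raw_rows: pd.DataFrame, proteome: Phosphoproteome) -> MappedExperiment:
    """Map raw experiment rows to reference sites, logging every outcome.

    Expects an ``accession`` column and either a ``site`` column (e.g.
    ``"Y1068"``) or ``residue`` + ``position`` columns. Rows whose site is
    absent from the reference are excluded (and logged); duplicate rows for
    one site are collapsed, keeping the maximum-magnitude value per numeric
    column so that any thresholded evidence is preserved.
    """
    if "accession" not in raw_rows.columns:
        raise SchemaError("experiment table missing required column 'accession'")
    has_site = "site" in raw_rows.columns
    has_rp = {"residue", "position"} <= set(raw_rows.columns)
    if not (has_site or has_rp):
        raise SchemaError(
            "experiment table needs a 'site' column or 'residue'+'position' columns"
        )
    id_cols = ["accession"] + (["site"] if has_site else ["residue", "position"])
    value_cols = [c for c in raw_rows.columns if c not in id_cols]

    log = []
    keys = []
    kept = []
    if len(raw_rows) == 0:
        warnings.warn("empty experiment table; empty mapping result", stacklevel=2)
    for i, (_, row) in enumerate(raw_rows.iterrows()):
        try:
            if has_site:
                parsed = _parse_site_descriptor(row["site"])
                if parsed is None:
                    log.append((i, "excluded", f"unparseable site descriptor {row['site']!r}"))
                    continue
                res, pos = parsed
            else:
                res, pos = row["residue"], row["position"]
            sid = canonicalize_site(row["accession"], res, int(pos))
        except (SiteValidationError, TypeError, ValueError) as exc:
            log.append((i, "excluded", str(exc)))
            continue
        if sid.key not in proteome:
            log.append((i, "excluded", f"{sid.key} not in reference phosphoproteome"))
            continue
        log.append((i, "mapped", sid.key))
        keys.append(sid.key)
        kept.append(row[value_cols])

    if kept:
        mapped = pd.DataFrame(kept)
        mapped.index = pd.Index(keys, name="site")
        if mapped.index.has_duplicates:
            # collapse duplicates: per column keep the max-magnitude value
            def _max_magnitude(col: pd.Series) -> float:
                vals = pd.to_numeric(col, errors="coerce").to_numpy()
                if np.isnan(vals).all():
                    return np.nan
                return vals[np.nanargmax(np.abs(vals))]

            for k in mapped.index[mapped.index.duplicated()].unique():
                log.append(
                    (-1, "collapsed", f"duplicate rows for {k} collapsed (max magnitude kept)")
                )
            mapped = mapped.groupby(level=0, sort=False).agg(_max_magnitude)
            mapped.index.name = "site"
    else:
        mapped = pd.DataFrame(columns=value_cols, index=pd.Index([], name="site"))

    log_df = pd.DataFrame(log, columns=["row", "outcome", "message"])
    return MappedExperiment(rows=mapped, mapping_log=log_df)


_COMPARATORS = {
    "ge": lambda v, t: v >= t,
    "le": lambda v, t: v <= t,
    "gt": lambda v, t: v > t,
    "lt": lambda v, t: v < t,
}


def binarize_evidence(
    exp: MappedExperiment,
    column: str,
    threshold: float,
    comparator: str = "ge",
    proteome: Phosphoproteome | None = None,
    residue_class: str | None = None,
    condition_name: str | None = None,
) -> EvidenceSet:
    """Threshold one quantification column into a binary evidence set.

    Sites whose (non-missing) value satisfies ``value <comparator> threshold``
    are included; missing values are treated as not observed. A warning is
    emitted when the evidence is smaller than the sizes typically needed for
    statistical power (50 Y sites / 1000 ST sites).
    """
    if column not in exp.rows.columns:
        raise SchemaError(f"unknown quantification column {column!r}")
    if comparator not in _COMPARATORS:
        raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")

    raw = exp.rows[column]
    values = pd.to_numeric(raw, errors="coerce")
    non_numeric = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if non_numeric.any():
        bad = list(exp.rows.index[non_numeric])[:3]
        raise ValueError(f"non-numeric values in column {column!r} at sites {bad}")

    mask = _COMPARATORS[comparator](values, threshold)
    mask &= values.notna()
    selected = frozenset(exp.rows.index[mask])

    if residue_class is None:
        classes = {SiteID.from_key(k).residue_class for k in selected} or (
            {SiteID.from_key(k).residue_class for k in exp.rows.index}
        )
        if len(classes) != 1:
            raise ValueError(
                "evidence mixes residue classes; pass residue_class explicitly "
                "or split the experiment by class first"
            )
        residue_class = classes.pop()
    selected = frozenset(
        k for k in selected if SiteID.from_key(k).residue_class == residue_class
    )

    name = condition_name or column
    if proteome is not None:
        ev = EvidenceSet.from_sites(name, selected, residue_class, proteome)
    else:
        ev = EvidenceSet(name, selected, residue_class, len(selected))

    minimum = LOW_EVIDENCE_Y if residue_class == "Y" else LOW_EVIDENCE_ST
    if len(ev.sites) < minimum:
        warnings.warn(
            f"evidence set {name!r} has {len(ev.sites)} {residue_class} sites; "
            f"{minimum} or more are typically needed for statistical power",
            stacklevel=2,
        )
    return ev
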
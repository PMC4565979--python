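"""Cross-link tables: parsing, deduplication, region categorization and
mapping onto structural models as Euclidean Cα–Cα distances.

A cross-link is an unordered pair of lysine (or, for synthetic data, any
residue) sites, each identified by ``(chain, seq_id)``, carried with the
nucleotide-state dataset it was detected in and a detection count.  "Total"
counts include redundant detections of the same pair (e.g. from miss-cleaved
peptides); "non-redundant" collapses to unique unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structio import StructureModel, ca_distance

__all__ = [
    "Site",
    "CrosslinkRecord",
    "CrosslinkSet",
    "RegionScheme",
    "load_crosslinks",
    "write_crosslinks",
    "map_distances",
    "categorize",
]

Site = tuple[str, int]

_COLUMNS = ["chain_a", "res_a", "chain_b", "res_b", "dataset", "count"]


def _ordered(a: Site, b: Site) -> tuple[Site, Site]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class CrosslinkRecord:
    """One linkage with unordered-pair semantics: the lexicographically
    smaller site is stored first, so (A10, B20) and (B20, A10) are equal."""

    site_a: Site
    site_b: Site
    dataset: str = ""
    count: int = 1

    def __post_init__(self):
        a = (str(self.site_a[0]), int(self.site_a[1]))
        b = (str(self.site_b[0]), int(self.site_b[1]))
        if a == b:
            raise ValueError(f"self-link not allowed: {a}")
        a, b = _ordered(a, b)
        object.__setattr__(self, "site_a", a)
        object.__setattr__(self, "site_b", b)
        if self.count < 1:
            raise ValueError("count must be ≥ 1")

    @property
    def pair(self) -> tuple[Site, Site]:
        return (self.site_a, self.site_b)


@dataclass
class CrosslinkSet:
    records: list[CrosslinkRecord] = field(default_factory=list)
    proxy_coordinates: dict[Site, np.ndarray] = field(default_factory=dict)

    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.dataset)
        return list(seen)

    def nonredundant(self, scope: str = "pooled") -> "CrosslinkSet":
        """Collapse to unique unordered pairs, each with count 1.

        ``scope='pooled'`` merges across datasets (the dataset label of the
        survivor is the first seen); ``scope='per-dataset'`` keeps one record
        per (pair, dataset).
        """
        if scope not in ("pooled", "per-dataset"):
            raise ValueError(f"unknown scope {scope!r}")
        seen: dict = {}
        for r in self.records:
            key = r.pair if scope == "pooled" else (r.pair, r.dataset)
            if key not in seen:
                seen[key] = CrosslinkRecord(r.site_a, r.site_b, r.dataset, 1)
        return CrosslinkSet(list(seen.values()), dict(self.proxy_coordinates))

    def subset(self, predicate) -> "CrosslinkSet":
        return CrosslinkSet(
            [r for r in self.records if predicate(r)], dict(self.proxy_coordinates)
        )

    def __len__(self) -> int:
        return len(self.records)


def load_crosslinks(
    path: str | Path, dataset_whitelist: set[str] | None = None
) -> CrosslinkSet:
    """Read a TSV cross-link table (columns chain_a, res_a, chain_b, res_b,
    dataset, count).  Unordered pairs are normalized at ingest and duplicate
    rows within a dataset merge by summing counts."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    merged: dict = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            ra, rb = int(row["res_a"]), int(row["res_b"])
            count = int(row["count"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: non-integer field ({exc})") from exc
        dataset = str(row["dataset"])
        if dataset_whitelist is not None and dataset not in dataset_whitelist:
            raise ValueError(f"{path}, line {line}: unknown dataset label {dataset!r}")
        rec = CrosslinkRecord((str(row["chain_a"]), ra), (str(row["chain_b"]), rb),
                              dataset, count)
        key = (rec.pair, rec.dataset)
        if key in merged:
            prev = merged[key]
            merged[key] = CrosslinkRecord(prev.site_a, prev.site_b, prev.dataset,
                                          prev.count + rec.count)
        else:
            merged[key] = rec
    return CrosslinkSet(list(merged.values()))


def write_crosslinks(cset: CrosslinkSet, path: str | Path) -> None:
    rows = [
        {
            "chain_a": r.site_a[0], "res_a": r.site_a[1],
            "chain_b": r.site_b[0], "res_b": r.site_b[1],
            "dataset": r.dataset, "count": r.count,
        }
        for r in cset.records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def map_distances(model: StructureModel, cset: CrosslinkSet) -> pd.DataFrame:
    """Per-record Euclidean Cα–Cα distance with a mapping status.

    Status is ``mapped`` when both endpoints are in the model, ``proxy-mapped``
    when at least one comes from the set's proxy coordinates (e.g. loop
    residues modeled from a homologous structure), and ``unmappable`` when an
    endpoint has no coordinate at all; unmappable records are retained and
    flagged, never dropped.
    """
    rows = []
    proxies = cset.proxy_coordinates
    for r in cset.records:
        in_model = [model.ca(*s) is not None for s in (r.site_a, r.site_b)]
        dist = ca_distance(model, r.site_a, r.site_b, proxy=proxies)
        if np.isnan(dist):
            status = "unmappable"
        elif all(in_model):
            status = "mapped"
        else:
            status = "proxy-mapped"
        rows.append({
            "chain_a": r.site_a[0], "res_a": r.site_a[1],
            "chain_b": r.site_b[0], "res_b": r.site_b[1],
            "dataset": r.dataset, "count": r.count,
            "distance": dist, "status": status,
        })
    return pd.DataFrame(rows, columns=_COLUMNS + ["distance", "status"])


# ---------------------------------------------------------------------------
# region categorization
# ---------------------------------------------------------------------------

class RegionScheme:
    """Named, non-overlapping residue ranges per chain.

    ``lobe_regions`` optionally names the two RecA-like lobes of an ATPase
    domain; a linkage with both endpoints inside lobe regions is then
    categorized ``intralobe`` (same lobe) or ``interlobe`` (different lobes),
    matching the usual bookkeeping for Swi2/Snf2 cross-link tables.
    """

    def __init__(
        self,
        regions: dict[str, list[tuple[str, int, int]]],
        lobe_regions: set[str] | None = None,
    ):
        self.regions = regions
        self.lobe_regions = set(lobe_regions or ())
        for chain, ranges in regions.items():
            spans = sorted((lo, hi, name) for name, lo, hi in ranges)
            for (lo1, hi1, n1), (lo2, hi2, n2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"chain {chain!r}: regions {n1!r} and {n2!r} overlap"
                    )

    @classmethod
    def from_dict(cls, data: dict) -> "RegionScheme":
        regions = {
            chain: [(str(r["name"]), int(r["start"]), int(r["end"])) for r in ranges]
            for chain, ranges in data.get("regions", {}).items()
        }
        return cls(regions, set(data.get("lobe_regions", ())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def region_of(self, site: Site) -> str | None:
        for name, lo, hi in self.regions.get(site[0], ()):
            if lo <= site[1] <= hi:
                return name
        return None

    def category(self, rec: CrosslinkRecord) -> str:
        ra, rb = self.region_of(rec.site_a), self.region_of(rec.site_b)
        if ra is None or rb is None:
            return "unassigned"
        if ra in self.lobe_regions and rb in self.lobe_regions:
            return "intralobe" if ra == rb else "interlobe"
        if ra == rb:
            return f"within {ra}"
        return "–".join(sorted((ra, rb)))  # en-dash joined pair


def categorize(
    cset: CrosslinkSet, scheme: RegionScheme
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each record to exactly one category from the unordered pair of
    its endpoint regions and tabulate per-dataset totals.

    Returns ``(table, summary)``: the per-record table with a ``category``
    column, and a summary with one row per (dataset, category) holding the
    total detection count and the non-redundant (unique pair) count.
    """
    rows = []
    for r in cset.records:
        rows.append({
            "chain_a": r.site_a[0], "res_a": r.site_a[1],
            "chain_b": r.site_b[0], "res_b": r.site_b[1],
            "dataset": r.dataset, "count": r.count,
            "category": scheme.category(r),
        })
    table = pd.DataFrame(rows, columns=_COLUMNS + ["category"])
    if table.empty:
        summary = pd.DataFrame(columns=["dataset", "category", "total", "nonredundant"])
        return table, summary
    grouped = table.groupby(["dataset", "category"], sort=True)
    summary = grouped.agg(
        total=("count", "sum"),
        nonredundant=("count", "size"),
    ).reset_index()
    # nonredundant must count unique unordered pairs, not rows
    uniq = (
        table.groupby(["dataset", "category"])
        .apply(
            lambda g: len({((a, ra), (b, rb)) for a, ra, b, rb in
                           zip(g.chain_a, g.res_a, g.chain_b, g.res_b)}),
            include_groups=False,
        )
        .rename("nonredundant")
        .reset_index()
    )
    summary = summary.drop(columns="nonredundant").merge(uniq, on=["dataset", "category"])
    return table, summary
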
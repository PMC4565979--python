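"""Conformational-state discrimination from inter-subdomain cross-links.

Given the Cα–Cα distance of each detected inter-lobe linkage on a set of
candidate conformer models (e.g. a Swi2/Snf2 ATPase in 'open', 'semi-closed'
and 'closed' states) together with per-nucleotide-dataset detection counts,
each linkage is classified against a distance cutoff — 30 Å by default, the
maximum Cα–Cα span bridgeable by a lysine–lysine cross-linker such as DSSG
plus two lysine side chains — and the conformers compatible with every
informative linkage of a dataset are intersected into a per-dataset verdict.

A linkage whose distances fall at or below the cutoff on every model (or
above it on every model) cannot distinguish the conformations; a linkage
detected in every dataset cannot tell the datasets apart and is flagged
non-informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConformerDistanceTable",
    "LinkageClass",
    "classify_linkages",
    "infer_state",
    "state_report",
    "detection_summary",
]

DEFAULT_CUTOFF = 30.0


class ConformerDistanceTable:
    """Per-linkage conformer distances and per-dataset detection counts.

    TSV layout: columns ``res_a``, ``res_b``, one ``d_<model>`` distance
    column per conformer model (Å; empty = unmappable on that model) and one
    ``n_<dataset>`` detection-count column per dataset.
    """

    def __init__(self, df: pd.DataFrame):
        for c in ("res_a", "res_b"):
            if c not in df.columns:
                raise ValueError(f"missing column {c!r}")
        self.df = df.reset_index(drop=True)
        self.models = [c[2:] for c in df.columns if c.startswith("d_")]
        self.datasets = [c[2:] for c in df.columns if c.startswith("n_")]
        if len(df) and not self.models:
            raise ValueError("need at least one d_<model> distance column")
        if len(df) and not self.datasets:
            raise ValueError("need at least one n_<dataset> count column")
        counts = df[[f"n_{d}" for d in self.datasets]].to_numpy(dtype=float) if len(df) else None
        if counts is not None and (counts.sum(axis=1) <= 0).any():
            raise ValueError("every linkage needs a positive count in some dataset")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConformerDistanceTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def distance(self, row: int, model: str) -> float:
        return float(self.df.loc[row, f"d_{model}"])

    def count(self, row: int, dataset: str) -> int:
        v = self.df.loc[row, f"n_{dataset}"]
        return 0 if pd.isna(v) else int(v)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LinkageClass:
    linkage: tuple[int, int]
    cls: str  # below-all | above-all | discriminating
    compatible_models: frozenset[str]
    informative: bool  # False when detected in every dataset
    counts: dict[str, int]
    excluded_models: frozenset[str]  # unmappable on these models

    @property
    def total_detections(self) -> int:
        return sum(self.counts.values())

    def detected_in(self, dataset: str) -> bool:
        return self.counts.get(dataset, 0) > 0


def classify_linkages(
    table: ConformerDistanceTable, cutoff: float = DEFAULT_CUTOFF
) -> list[LinkageClass]:
    """Classify every linkage against the cutoff (inclusive: a distance equal
    to the cutoff is compatible).

    ``below-all``: compatible with every (mappable) model; ``above-all``:
    compatible with none; ``discriminating``: compatible with a proper,
    non-empty subset.  Models on which a linkage is unmappable are excluded
    from that linkage's verdict and flagged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = []
    for i in range(len(table)):
        row = table.df.loc[i]
        excluded, compatible = set(), set()
        for m in table.models:
            d = row[f"d_{m}"]
            if pd.isna(d):
                excluded.add(m)
            elif float(d) <= cutoff:
                compatible.add(m)
        considered = set(table.models) - excluded
        if compatible == considered:
            cls = "below-all"
        elif not compatible:
            cls = "above-all"
        else:
            cls = "discriminating"
        counts = {d: table.count(i, d) for d in table.datasets}
        informative = any(c == 0 for c in counts.values())
        out.append(
            LinkageClass(
                (int(row["res_a"]), int(row["res_b"])),
                cls,
                frozenset(compatible),
                informative,
                counts,
                frozenset(excluded),
            )
        )
    return out


def detection_summary(classes: list[LinkageClass]) -> dict:
    """Aggregate detection counts by class (the bookkeeping behind statements
    like "18 cross-links do not distinguish, 14 below and 4 above")."""
    below = [c for c in classes if c.cls == "below-all"]
    above = [c for c in classes if c.cls == "above-all"]
    disc = [c for c in classes if c.cls == "discriminating"]
    return {
        "total_detections": sum(c.total_detections for c in classes),
        "below_all_detections": sum(c.total_detections for c in below),
        "above_all_detections": sum(c.total_detections for c in above),
        "nondistinguishing_detections": sum(c.total_detections for c in below + above),
        "discriminating_sites": len(disc),
        "discriminating_noninformative_sites": sum(1 for c in disc if not c.informative),
        "discriminating_informative_sites": sum(1 for c in disc if c.informative),
        "informative_detections": sum(
            c.total_detections for c in disc if c.informative
        ),
    }


def infer_state(
    classes: list[LinkageClass], datasets: list[str], all_models: set[str] | None = None
) -> dict[str, dict]:
    """Per-dataset conformer verdict by intersecting compatible-model sets of
    the discriminating, informative linkages detected in that dataset.

    With no supporting linkage the verdict is "all models" (the data cannot
    narrow the state); a non-empty support whose intersection is empty reports
    "no single model consistent" rather than failing.
    """
    if all_models is None:
        all_models = set()
        for c in classes:
            all_models |= c.compatible_models | c.excluded_models
    report: dict[str, dict] = {}
    for ds in datasets:
        support = [
            c for c in classes
            if c.cls == "discriminating" and c.informative and c.detected_in(ds)
        ]
        if support:
            consistent = frozenset.intersection(*(c.compatible_models for c in support))
            verdict = (
                sorted(consistent) if consistent else "no single model consistent"
            )
        else:
            consistent = frozenset(all_models)
            verdict = "all models"
        report[ds] = {
            "consistent_models": sorted(consistent),
            "verdict": verdict,
            "supporting_sites": len(support),
            "supporting_crosslink_total": sum(c.total_detections for c in support),
        }
    return report


def state_report(
    classes: list[LinkageClass],
    per_dataset: dict[str, dict],
    out_dir: str | Path,
    prefix: str = "confstate",
) -> tuple[Path, Path]:
    """Serialize classification and verdicts to TSV + JSON with stable
    ordering (byte-identical across reruns on the same input)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "res_a": c.linkage[0],
            "res_b": c.linkage[1],
            "class": c.cls,
            "compatible_models": ",".join(sorted(c.compatible_models)),
            "informative": c.informative,
            "total_detections": c.total_detections,
            **{f"n_{d}": n for d, n in sorted(c.counts.items())},
        }
        for c in sorted(classes, key=lambda c: c.linkage)
    ]
    tsv_path = out_dir / f"{prefix}_linkages.tsv"
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    json_path = out_dir / f"{prefix}_verdicts.json"
    with open(json_path, "w") as fh:
        json.dump(per_dataset, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path
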
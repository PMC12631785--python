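"""Annotation-overlap analysis between feature spans and predicted sites.

Intersects 1-based inclusive residue feature spans with per-protein
predicted binding-site sets and reports, per (feature name, task), the
fraction of feature-carrying proteins with at least one overlapping
residue. Records can be gated on structure quality (pLDDT > 70, PAE < 10,
both strict).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

from .registry import TASKS


class OverlapError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpan:
    protein_id: str
    feature_name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise OverlapError(
                f"invalid span {self.start}-{self.end} for {self.protein_id}"
            )


@dataclass(frozen=True)
class QualityGate:
    min_plddt: float = 70.0
    max_pae: float = 10.0


def overlap(span: FeatureSpan, predicted: set[int]) -> set[int]:
    """Residue positions shared by the span and the predicted set (1-based)."""
    return {p for p in predicted if span.start <= p <= span.end}


def proportion_with_overlap(
    features: list[FeatureSpan],
    predictions: dict[str, dict[str, set[int]]],
    tasks: tuple[str, ...] = TASKS,
) -> dict[str, dict[str, float | None]]:
    """Table feature_name x task -> fraction of proteins with >= 1 overlapping
    residue; ``predictions`` maps protein_id -> task -> predicted positions.

    A single overlapping residue qualifies a protein. Denominator is the
    number of distinct proteins carrying the feature; empty denominators
    report None.
    """
    by_feature: dict[str, dict[str, list[FeatureSpan]]] = {}
    for span in features:
        by_feature.setdefault(span.feature_name, {}).setdefault(
            span.protein_id, []
        ).append(span)

    table: dict[str, dict[str, float | None]] = {}
    for feature_name, proteins in by_feature.items():
        row: dict[str, float | None] = {}
        for task in tasks:
            denom = len(proteins)
            if denom == 0:
                row[task] = None
                continue
            num = 0
            for protein_id, spans in proteins.items():
                pred = predictions.get(protein_id, {}).get(task, set())
                if any(overlap(s, pred) for s in spans):
                    num += 1
            row[task] = num / denom
        table[feature_name] = row
    return table


def quality_filter(
    records: list[dict], gate: QualityGate | None = None
) -> list[dict]:
    """Keep records with plddt > gate.min_plddt and pae < gate.max_pae
    (both strict); records missing either scalar are skipped with a warning."""
    gate = gate or QualityGate()
    kept = []
    for rec in records:
        plddt, pae = rec.get("plddt"), rec.get("pae")
        if plddt is None or pae is None:
            warnings.warn(
                f"record {rec.get('protein_id', '?')} missing quality scalar; skipped",
                stacklevel=2,
            )
            continue
        if plddt > gate.min_plddt and pae < gate.max_pae:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_spans(path: str | Path) -> list[FeatureSpan]:
    spans = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            spans.append(FeatureSpan(
                protein_id=row["protein_id"],
                feature_name=row["feature_name"],
                start=int(row["start"]),
                end=int(row["end"]),
            ))
    return spans


def read_predictions(path: str | Path, threshold: float = 0.5) -> dict[str, dict[str, set[int]]]:
    """TSV with columns protein_id, position (1-based), one column per task
    holding probabilities or 0/1 calls."""
    preds: dict[str, dict[str, set[int]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["protein_id"]
            pos = int(row["position"])
            entry = preds.setdefault(pid, {t: set() for t in TASKS})
            for task in TASKS:
                if task in row and float(row[task]) > threshold:
                    entry[task].add(pos)
    return preds


def write_proportion_table(
    table: dict[str, dict[str, float | None]], path: str | Path,
    tasks: tuple[str, ...] = TASKS,
) -> None:
    with open(path, "w") as fh:
        fh.write("feature_name\t" + "\t".join(tasks) + "\n")
        for feature_name in sorted(table):
            cells = [
                "NA" if table[feature_name][t] is None else f"{table[feature_name][t]:.6f}"
                for t in tasks
            ]
            fh.write(feature_name + "\t" + "\t".join(cells) + "\n")
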
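"""Molecule registry: the catalogue of partner molecule types used for labeling.

The default registry ships 79 components split into five categories
(20 amino acids, 8 nucleotides, 16 ions, 31 ligands, 4 lipids). Users may
point any entry point at a replacement TSV with the same two-column layout
(``comp_id``, ``category``); the per-category counts are only enforced for
the default file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

CATEGORIES = ("amino_acid", "nucleotide", "ion", "ligand", "lipid")

#: category sizes of the default registry, enforced at load time
DEFAULT_CATEGORY_COUNTS = {
    "amino_acid": 20,
    "nucleotide": 8,
    "ion": 16,
    "ligand": 31,
    "lipid": 4,
}

#: task names in model output order; nucleotide partners feed the "nucleic" task
TASKS = ("protein", "nucleic", "ligand", "ion", "lipid")

_CATEGORY_TO_TASK = {
    "amino_acid": "protein",
    "nucleotide": "nucleic",
    "ligand": "ligand",
    "ion": "ion",
    "lipid": "lipid",
}


class RegistryError(ValueError):
    """Raised when a registry file violates the registry invariants."""


@dataclass(frozen=True)
class MoleculeRegistry:
    """Ordered map from component id to partner category.

    ``columns`` (file order) fixes the column ordering of the 20x79
    interface-type matrix.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp, cat in self.entries.items():
            if cat not in CATEGORIES:
                raise RegistryError(f"unknown category {cat!r} for {comp!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, comp_id: str) -> bool:
        return comp_id in self.entries

    def category(self, comp_id: str) -> str | None:
        """Category of ``comp_id``, or ``None`` if unregistered."""
        return self.entries.get(comp_id)

    def task(self, comp_id: str) -> str | None:
        cat = self.entries.get(comp_id)
        return _CATEGORY_TO_TASK[cat] if cat is not None else None

    @property
    def columns(self) -> list[str]:
        """Component ids in file order (interface-matrix column order)."""
        return list(self.entries)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for cat in self.entries.values():
            counts[cat] += 1
        return counts

    def comp_ids(self, category: str) -> list[str]:
        return [c for c, cat in self.entries.items() if cat == category]

    @classmethod
    def from_tsv(cls, path: str | Path, *, enforce_counts: bool = False) -> "MoleculeRegistry":
        entries: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or set(reader.fieldnames) < {"comp_id", "category"}:
                raise RegistryError(f"{path}: expected columns comp_id, category")
            for row in reader:
                comp = row["comp_id"].strip()
                if comp in entries:
                    raise RegistryError(f"{path}: duplicate comp_id {comp!r}")
                entries[comp] = row["category"].strip()
        reg = cls(entries)
        if enforce_counts:
            counts = reg.category_counts()
            if counts != DEFAULT_CATEGORY_COUNTS:
                raise RegistryError(
                    f"registry category counts {counts} != expected {DEFAULT_CATEGORY_COUNTS}"
                )
        return reg

    @classmethod
    def default(cls) -> "MoleculeRegistry":
        """The shipped 79-entry registry (counts asserted)."""
        with resources.as_file(resources.files("mpbind.data") / "registry.tsv") as p:
            return cls.from_tsv(p, enforce_counts=True)


def load_registry(path: str | Path | None = None) -> MoleculeRegistry:
    """Load a registry TSV, or the shipped default when ``path`` is None."""
    if path is None:
        return MoleculeRegistry.default()
    return MoleculeRegistry.from_tsv(path)
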
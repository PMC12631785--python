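"""Heavy-atom contact computation and per-residue task labels.

Two molecules are in contact when the minimum distance between their heavy
atoms is within the cutoff (5 A by default, inclusive). Contacts against the
registry's partner categories are reduced to five per-residue binary task
vectors (protein, nucleic, ligand, ion, lipid); DNA and RNA partners merge
into the single nucleic task.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .registry import TASKS, MoleculeRegistry
from .structure_io import (
    AA_ROW_ORDER,
    Atom,
    Chain,
    ComplexStructure,
    PartnerEntity,
)

DEFAULT_CUTOFF = 5.0

_CATEGORY_TO_TASK = {
    "amino_acid": "protein",
    "nucleotide": "nucleic",
    "ligand": "ligand",
    "ion": "ion",
    "lipid": "lipid",
}


class LabelingError(ValueError):
    pass


@dataclass(frozen=True)
class ContactRecord:
    """One (target residue, partner) pair at min heavy-atom distance <= cutoff.

    ``partner`` is a :class:`PartnerEntity` for non-protein partners, or a
    ``(chain_id, residue_index)`` tuple for a foreign protein residue.
    """

    residue_index: int
    partner: object
    partner_comp: str
    category: str
    min_distance: float


@dataclass
class InterfaceMatrix:
    """20 x 79 binary amino-acid x molecule-type contact matrix."""

    values: np.ndarray
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]


@dataclass
class InterfaceLabels:
    chain_id: str
    vectors: dict[str, np.ndarray]  # task -> (L,) int array

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.vectors[t] for t in TASKS], axis=1)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def min_heavy_distance(a: list[Atom] | np.ndarray, b: list[Atom] | np.ndarray) -> float:
    """Minimum Euclidean distance over all cross pairs of two heavy-atom sets."""
    pa = a if isinstance(a, np.ndarray) else np.array([x.coords for x in a], dtype=float)
    pb = b if isinstance(b, np.ndarray) else np.array([x.coords for x in b], dtype=float)
    if pa.size == 0 or pb.size == 0:
        raise LabelingError("minimum distance undefined for an empty atom set")
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


def _residue_atom_table(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coords of a chain with their residue indices."""
    coords, idx = [], []
    for res in chain.residues:
        for a in res.heavy_atoms:
            coords.append(a.coords)
            idx.append(res.index)
    if not coords:
        raise LabelingError(f"chain {chain.chain_id}: no heavy atoms")
    return np.asarray(coords, dtype=float), np.asarray(idx, dtype=int)


def compute_contacts(
    target: Chain,
    s: ComplexStructure,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ContactRecord]:
    """All contacts of ``target`` against partner entities and foreign chains.

    Uses a KD-tree (grid-accelerated) pair search; exact against the brute
    force O(n^2) definition.
    """
    if target not in s.chains:
        raise LabelingError(
            f"target chain {target.chain_id!r} is not part of structure {s.source_id!r}"
        )
    t_coords, t_res = _residue_atom_table(target)
    t_tree = cKDTree(t_coords)
    records: list[ContactRecord] = []

    def _pair_min(p_coords: np.ndarray, p_key: np.ndarray | None):
        """min distance per (target residue, partner key) using the KD trees"""
        p_tree = cKDTree(p_coords)
        dist = t_tree.sparse_distance_matrix(p_tree, max_distance=cutoff, output_type="coo_matrix")
        best: dict[tuple[int, int], float] = {}
        for ai, aj, d in zip(dist.row, dist.col, dist.data):
            key = (int(t_res[ai]), int(p_key[aj]) if p_key is not None else 0)
            if d < best.get(key, np.inf):
                best[key] = float(d)
        return best

    # non-protein partners: one record per (residue, entity)
    for ent in s.partners:
        p_coords = np.array([a.coords for a in ent.atoms], dtype=float)
        if p_coords.size == 0:
            continue
        for (ri, _), d in sorted(_pair_min(p_coords, None).items()):
            records.append(ContactRecord(
                residue_index=ri, partner=ent, partner_comp=ent.comp_id,
                category=ent.category, min_distance=d,
            ))

    # foreign protein chains: one record per (residue, foreign residue)
    for other in s.chains:
        if other is target:
            continue
        o_coords, o_res = _residue_atom_table(other)
        comp_by_idx = {r.index: r.comp_id for r in other.residues}
        for (ri, rj), d in sorted(_pair_min(o_coords, o_res).items()):
            records.append(ContactRecord(
                residue_index=ri, partner=(other.chain_id, rj),
                partner_comp=comp_by_idx[rj], category="amino_acid",
                min_distance=d,
            ))
    return records


def compute_contacts_bruteforce(
    target: Chain, s: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> list[ContactRecord]:
    """O(n^2) reference path for the grid-accelerated :func:`compute_contacts`."""
    records: list[ContactRecord] = []
    for res in target.residues:
        if not res.heavy_atoms:
            continue
        for ent in s.partners:
            d = min_heavy_distance(res.heavy_atoms, ent.atoms)
            if d <= cutoff:
                records.append(ContactRecord(res.index, ent, ent.comp_id,
                                             ent.category, d))
        for other in s.chains:
            if other is target:
                continue
            for fres in other.residues:
                if not fres.heavy_atoms:
                    continue
                d = min_heavy_distance(res.heavy_atoms, fres.heavy_atoms)
                if d <= cutoff:
                    records.append(ContactRecord(
                        res.index, (other.chain_id, fres.index), fres.comp_id,
                        "amino_acid", d))
    return records


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def build_interface_matrix(
    contacts: list[ContactRecord], target: Chain, registry: MoleculeRegistry
) -> InterfaceMatrix:
    """OR-reduce contacts onto the 20 x 79 amino-acid x molecule matrix."""
    cols = registry.columns
    col_index = {c: j for j, c in enumerate(cols)}
    row_index = {aa: i for i, aa in enumerate(AA_ROW_ORDER)}
    mat = np.zeros((len(AA_ROW_ORDER), len(cols)), dtype=int)
    one_letter = {r.index: r.one_letter for r in target.residues}
    for rec in contacts:
        if rec.partner_comp not in col_index:
            raise LabelingError(
                f"contact references unregistered molecule {rec.partner_comp!r}"
            )
        aa = one_letter.get(rec.residue_index, "X")
        if aa in row_index:
            mat[row_index[aa], col_index[rec.partner_comp]] = 1
    return InterfaceMatrix(values=mat, row_order=AA_ROW_ORDER, col_order=tuple(cols))


def reduce_to_task_labels(contacts: list[ContactRecord], target: Chain) -> InterfaceLabels:
    """Collapse contacts to the five per-residue binary task vectors."""
    L = len(target)
    vectors = {t: np.zeros(L, dtype=int) for t in TASKS}
    for rec in contacts:
        task = _CATEGORY_TO_TASK.get(rec.category)
        if task is not None:
            vectors[task][rec.residue_index] = 1
    return InterfaceLabels(chain_id=target.chain_id, vectors=vectors)


def label_chain(
    target: Chain,
    s: ComplexStructure,
    registry: MoleculeRegistry,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[InterfaceLabels, InterfaceMatrix]:
    contacts = compute_contacts(target, s, cutoff)
    return (
        reduce_to_task_labels(contacts, target),
        build_interface_matrix(contacts, target, registry),
    )


def dataset_filter(
    chains: list[tuple[Chain, int]],
    max_atoms: int = 8192,
    min_residues: int = 48,
) -> list[Chain]:
    """Keep chains with atom_count <= 8192 and residue count >= 48."""
    return [c for c, n_atoms in chains
            if n_atoms <= max_atoms and len(c) >= min_residues]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def labels_to_tsv(labels: InterfaceLabels, target: Chain, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tauthor_number\t" + "\t".join(TASKS) + "\n")
        for res in target.residues:
            row = "\t".join(str(int(labels.vectors[t][res.index])) for t in TASKS)
            fh.write(f"{labels.chain_id}\t{res.author_number}\t{row}\n")


def labels_to_bed(labels: InterfaceLabels, path: str | Path) -> None:
    """BED-like intervals (0-based half-open over residue indices) per task."""
    with open(path, "w") as fh:
        for task in TASKS:
            y = labels.vectors[task]
            start = None
            for i, v in enumerate(y):
                if v and start is None:
                    start = i
                elif not v and start is not None:
                    fh.write(f"{labels.chain_id}\t{start}\t{i}\t{task}\n")
                    start = None
            if start is not None:
                fh.write(f"{labels.chain_id}\t{start}\t{len(y)}\t{task}\n")


def matrix_to_tsv(matrix: InterfaceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("aa\t" + "\t".join(matrix.col_order) + "\n")
        for i, aa in enumerate(matrix.row_order):
            fh.write(aa + "\t" + "\t".join(map(str, matrix.values[i])) + "\n")
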
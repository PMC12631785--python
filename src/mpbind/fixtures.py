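"""Deterministic synthetic complexes and training datasets.

Backbones are grown from ideal internal coordinates (N-CA 1.46 A, CA-C
1.52 A, C-N 1.33 A, ideal angles, omega 180) with NeRF chain extension;
partner entities are planted so that the nearest heavy atom of the anchor
residue sits at exactly the requested distance. Generated complexes are
written as real mmCIF files and re-read through the parser so the full I/O
path is exercised. Ground-truth labels are computed with plain O(n^2) NumPy
distances, independent of the labeling module.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .registry import TASKS, MoleculeRegistry, load_registry
from .structure_io import (
    Atom,
    Chain,
    ComplexStructure,
    Residue,
    classify_entities,
    parse_structure,
    preprocess,
    write_structure,
)

# ideal backbone internal coordinates
_B_N_CA = 1.46
_B_CA_C = 1.52
_B_C_N = 1.33
_B_C_O = 1.23
_B_CA_CB = 1.53
_ANG_N_CA_C = 111.0
_ANG_CA_C_N = 116.5
_ANG_C_N_CA = 121.5

GEOMETRIES = ("ideal_helix", "extended", "random_walk")
_PHI_PSI = {"ideal_helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedPartner:
    category: str
    comp_id: str
    anchor: int            # residue index in the target chain
    distance: float        # min heavy-atom distance to the anchor residue, A
    target_chain: int = 0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("planted distance must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_chains: int = 1
    n_residues: int = 30
    partners: tuple[PlantedPartner, ...] = ()
    geometry: str = "ideal_helix"

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        for p in self.partners:
            if not (0 <= p.anchor < self.n_residues):
                raise ValueError(f"anchor {p.anchor} outside chain of {self.n_residues}")
            if not (0 <= p.target_chain < self.n_chains):
                raise ValueError("target_chain out of range")


# ---------------------------------------------------------------------------
# backbone construction (NeRF)
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a new atom d bonded to c, given chain a-b-c (NeRF)."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.cos(dih) * np.sin(ang),
        bond * np.sin(dih) * np.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(n_residues: int, geometry: str, rng: np.random.Generator,
                   sequence: str | None = None) -> list[Residue]:
    """Grow an all-ALA (or given-sequence GLY/ALA) backbone with CB side chains."""
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")

    if geometry in _PHI_PSI:
        phis = np.full(n_residues, _PHI_PSI[geometry][0])
        psis = np.full(n_residues, _PHI_PSI[geometry][1])
    else:  # random_walk over a broad allowed region
        phis = rng.uniform(-150.0, -60.0, n_residues)
        psis = rng.uniform(-70.0, 150.0, n_residues)

    coords: list[dict[str, np.ndarray]] = []
    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANG_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = coords[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _ANG_CA_C_N, psis[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _B_N_CA, _ANG_C_N_CA, 180.0)
        c_i = _place_atom(prev["C"], n_i, ca_i, _B_CA_C, _ANG_N_CA_C, phis[i])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O: anti-planar to the next N (psi - 180); last residue uses psi
    for i, c in enumerate(coords):
        c["O"] = _place_atom(c["N"], c["CA"], c["C"], _B_C_O, 120.5, psis[i] - 180.0)
        if sequence[i] != "G":
            c["CB"] = _place_atom(c["C"], c["N"], c["CA"], _B_CA_CB, 110.4, 122.5)

    residues = []
    for i, c in enumerate(coords):
        comp = "GLY" if sequence[i] == "G" else "ALA"
        atoms = [Atom("N", "N", c["N"]), Atom("CA", "C", c["CA"]),
                 Atom("C", "C", c["C"]), Atom("O", "O", c["O"])]
        if "CB" in c:
            atoms.append(Atom("CB", "C", c["CB"]))
        residues.append(Residue(comp_id=comp, one_letter=sequence[i],
                                author_number=str(i + 1), index=i, atoms=atoms))
    return residues


def _rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, 3)


_PARTNER_TEMPLATES = {
    # local offsets (A) and elements for small partner entities
    "ion": ([np.zeros(3)], None),
    "ligand": ([np.zeros(3), np.array([1.4, 0, 0]), np.array([2.4, 1.0, 0]),
                np.array([1.4, -1.2, 0.6])], ["C", "N", "O", "C"]),
    "lipid": ([np.array([1.3 * k, 0.25 * (-1) ** k, 0.0]) for k in range(5)],
              ["C"] * 5),
    "nucleotide": ([np.zeros(3), np.array([1.6, 0, 0]), np.array([2.8, 1.1, 0]),
                    np.array([1.6, -1.3, 0.5]), np.array([3.9, 0.4, 0.9])],
                   ["P", "O", "C", "C", "N"]),
}

_ION_ELEMENTS = {"ZN": "ZN", "MG": "MG", "CA": "CA", "NA": "NA", "K": "K",
                 "FE": "FE", "FE2": "FE", "MN": "MN", "CU": "CU", "CO": "CO",
                 "NI": "NI", "CD": "CD", "CL": "CL", "IOD": "I", "BR": "BR",
                 "HG": "HG"}


def _chain_coords(residues: list[Residue]) -> np.ndarray:
    return np.concatenate([r.coords() for r in residues])


def _min_dist(points_a: np.ndarray, points_b: np.ndarray) -> float:
    diff = points_a[:, None, :] - points_b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


def _template_points(partner: PlantedPartner) -> tuple[np.ndarray, list[str]]:
    offsets, elements = _PARTNER_TEMPLATES[
        partner.category if partner.category in _PARTNER_TEMPLATES else "ligand"
    ]
    if elements is None:
        elements = [_ION_ELEMENTS.get(partner.comp_id, "ZN")]
    return np.asarray(offsets, dtype=float), elements


def _place_points(partner: PlantedPartner, target: list[Residue],
                  all_chains: list[list[Residue]],
                  template: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Solve for a rigid placement of ``template`` points such that the
    anchor residue's min heavy-atom distance equals ``partner.distance``
    exactly, while every other residue stays beyond the 5 A contact cutoff
    (for plantings at <= 5 A) and beyond 1 A (clash) otherwise."""
    anchor_res = target[partner.anchor]
    anchor_atom = anchor_res.atom("CB") or anchor_res.atom("CA")
    anchor_pos = anchor_atom.coords
    anchor_coords = anchor_res.coords()
    all_coords = np.concatenate([_chain_coords(ch) for ch in all_chains])
    # escape direction: away from the local neighbourhood of the anchor
    near = all_coords[np.linalg.norm(all_coords - anchor_pos, axis=1) < 10.0]
    base_dir = anchor_pos - near.mean(axis=0)
    nb = np.linalg.norm(base_dir)
    base_dir = base_dir / nb if nb > 1e-6 else np.array([1.0, 0.0, 0.0])

    other_residues = [r for ch in all_chains for r in ch if r is not anchor_res]
    other_coords = _chain_coords(other_residues) if other_residues else None

    for attempt in range(100):
        if attempt == 0:
            u = base_dir
        else:
            u = base_dir + rng.normal(scale=0.4 + 0.01 * attempt, size=3)
            u /= np.linalg.norm(u)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        local = template @ np.stack([u, v, w])  # template laid out along +u

        def pts_at(t: float) -> np.ndarray:
            return anchor_pos + t * u + local

        # bisection on the offset along u for the exact anchor distance
        lo, hi = 0.0, partner.distance + 2.0
        while _min_dist(anchor_coords, pts_at(hi)) < partner.distance and hi < 1e3:
            hi *= 2.0
        if _min_dist(anchor_coords, pts_at(lo)) > partner.distance:
            continue
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _min_dist(anchor_coords, pts_at(mid)) < partner.distance:
                lo = mid
            else:
                hi = mid
        pts = pts_at(hi)
        if abs(_min_dist(anchor_coords, pts) - partner.distance) > 1e-9:
            continue
        if other_coords is not None:
            d_other = _min_dist(other_coords, pts)
            if partner.distance <= 5.0 and d_other <= 5.0 + 0.05:
                continue  # would contaminate another residue's label
            if d_other < 1.0:
                continue  # clash
        return pts
    raise PlacementError(
        f"could not place {partner.comp_id} at {partner.distance} A from "
        f"residue {partner.anchor} after 100 tries"
    )


def _place_partner(partner: PlantedPartner, target: list[Residue],
                   all_chains: list[list[Residue]],
                   rng: np.random.Generator) -> list[Atom]:
    template, elements = _template_points(partner)
    pts = _place_points(partner, target, all_chains, template, rng)
    return [Atom(f"{el}{k+1}" if len(pts) > 1 else el, el, pts[k])
            for k, el in enumerate(elements)]


def _place_partner_chain(partner: PlantedPartner, target: list[Residue],
                         all_chains: list[list[Residue]],
                         rng: np.random.Generator,
                         n_residues: int = 4) -> list[Residue]:
    """Plant a small protein chain whose nearest heavy atom to the anchor
    residue sits at exactly the requested distance."""
    mini = build_backbone(n_residues, "extended", rng, sequence="G" * n_residues)
    coords = _chain_coords(mini)
    template = coords - coords.mean(axis=0)
    pts = _place_points(partner, target, all_chains, template, rng)
    delta = pts - coords  # per-atom displacement of the solved rigid placement
    k = 0
    for res in mini:
        for a in res.atoms:
            a.coords = a.coords + delta[k]
            k += 1
    return mini


# ---------------------------------------------------------------------------
# complex generation
# ---------------------------------------------------------------------------

def _ground_truth(spec: FixtureSpec, chains: dict[str, list[Residue]],
                  partner_records: list[tuple[PlantedPartner, list[Atom], str]],
                  cutoff: float = 5.0) -> dict[str, np.ndarray]:
    """Brute-force O(n^2) labels from raw coordinates (labeling-module-free)."""
    labels: dict[str, np.ndarray] = {}
    chain_ids = list(chains)
    for cid in chain_ids:
        L = len(chains[cid])
        labels[cid] = np.zeros((L, len(TASKS)), dtype=int)
    task_index = {t: k for k, t in enumerate(TASKS)}
    # protein-protein: pairwise residue distances across chains
    for ai, cid_a in enumerate(chain_ids):
        for cid_b in chain_ids:
            if cid_a == cid_b:
                continue
            coords_b = _chain_coords(chains[cid_b])
            for i, res in enumerate(chains[cid_a]):
                if _min_dist(res.coords(), coords_b) <= cutoff:
                    labels[cid_a][i, task_index["protein"]] = 1
    # planted non-protein partners
    cat_to_task = {"ion": "ion", "ligand": "ligand", "lipid": "lipid",
                   "nucleotide": "nucleic"}
    for planted, atoms, target_cid in partner_records:
        pts = np.array([a.coords for a in atoms])
        t = task_index[cat_to_task[planted.category]]
        for cid in chain_ids:
            for i, res in enumerate(chains[cid]):
                if _min_dist(res.coords(), pts) <= cutoff:
                    labels[cid][i, t] = 1
    return labels


def make_complex(
    spec: FixtureSpec,
    out_path: str | Path | None = None,
    registry: MoleculeRegistry | None = None,
) -> tuple[ComplexStructure, dict[str, np.ndarray]]:
    """Generate a synthetic complex and its ground-truth labels.

    Returns the *classified* structure (re-read from a real mmCIF file) and
    a map chain_id -> (L, 5) int label matrix in task order
    ``("protein", "nucleic", "ligand", "ion", "lipid")``.
    """
    rng = np.random.default_rng(spec.seed)
    registry = registry or load_registry()

    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    chains: dict[str, list[Residue]] = {}
    next_x = 0.0
    for k, cid in enumerate(chain_ids):
        residues = build_backbone(spec.n_residues, spec.geometry, rng)
        coords = _chain_coords(residues)
        centroid = coords.mean(axis=0)
        radius = float(np.linalg.norm(coords - centroid, axis=1).max())
        rot, _ = _rigid(rng)
        shift = np.array([next_x + radius, 0.0, 0.0])
        next_x += 2.0 * radius + 25.0  # chains never within contact range
        for r in residues:
            for a in r.atoms:
                a.coords = rot @ (a.coords - centroid) + shift
        chains[cid] = residues

    partner_records: list[tuple[PlantedPartner, list[Atom], str]] = []
    extra_chain_ord = ord("A") + spec.n_chains
    for planted in spec.partners:
        target_cid = chain_ids[planted.target_chain]
        if planted.category == "amino_acid":
            mini = _place_partner_chain(planted, chains[target_cid],
                                        list(chains.values()), rng)
            chains[chr(extra_chain_ord)] = mini
            extra_chain_ord += 1
            continue
        atoms = _place_partner(planted, chains[target_cid],
                               list(chains.values()), rng)
        partner_records.append((planted, atoms, target_cid))

    labels = _ground_truth(spec, chains, partner_records)

    # assemble and write as mmCIF, then re-read through the parser
    raw = ComplexStructure(
        chains=[Chain(chain_id=cid, residues=res) for cid, res in chains.items()],
        source_id=f"fixture-{spec.seed}",
    )
    het_cid = chr(extra_chain_ord)
    for num, (planted, atoms, _) in enumerate(partner_records, start=1):
        if planted.category == "nucleotide":
            # nucleic partners are their own polymer chain
            nuc_cid = chr(extra_chain_ord + num)
            raw.chains.append(Chain(chain_id=nuc_cid, residues=[
                Residue(planted.comp_id, "X", "1", 0, atoms=atoms, hetero=False)
            ]))
        else:
            raw.chains.append(Chain(chain_id=het_cid, residues=[
                Residue(planted.comp_id, "X", str(num), 0, atoms=atoms, hetero=True)
            ]))

    if out_path is None:
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "fixture.cif"
            write_structure(raw, path)
            parsed = parse_structure(path, format="mmcif")
    else:
        path = Path(out_path)
        write_structure(raw, path)
        parsed = parse_structure(path, format="mmcif")
    structure = classify_entities(preprocess(parsed), registry)
    structure.source_id = raw.source_id
    return structure, labels


# ---------------------------------------------------------------------------
# learnable training task
# ---------------------------------------------------------------------------

@dataclass
class TrainingExample:
    chain_id: str
    graph: "object"               # ResidueGraph (import-cycle-free)
    labels: np.ndarray            # (L, 5) int
    mask: np.ndarray              # (L, 5) float


def make_training_task(
    seed: int,
    n_chains: int,
    n_residues: int = 200,
    positive_fraction: float = 0.10,
    signal_scale: float = 3.0,
    task: str = "ion",
    signal_dims: int = 16,
) -> list[TrainingExample]:
    """A separable synthetic dataset: binding residues get an additive offset
    in the first ``signal_dims`` stub-embedding dimensions.

    Labels are planted directly (no geometric partners needed); roughly
    ``positive_fraction`` of residues per chain are positive in ``task``.
    """
    from .graph_features import NodeFeatureConfig, StubEmbedder, featurize_chain

    rng = np.random.default_rng(seed)
    task_idx = TASKS.index(task)
    cfg = NodeFeatureConfig()
    providers = {
        "prottrans": StubEmbedder("prottrans"),
        "prostt5_aa": StubEmbedder("prostt5_aa"),
    }
    examples: list[TrainingExample] = []
    for k in range(n_chains):
        chain_seed = int(rng.integers(0, 2 ** 31))
        chain_rng = np.random.default_rng(chain_seed)
        residues = build_backbone(n_residues, "ideal_helix", chain_rng)
        chain = Chain(chain_id="A", residues=residues)
        for r in residues:
            from .structure_io import compute_virtual_atoms
            compute_virtual_atoms(r)
        n_pos = max(1, int(round(positive_fraction * n_residues)))
        pos = chain_rng.choice(n_residues, size=n_pos, replace=False)
        labels = np.zeros((n_residues, len(TASKS)), dtype=int)
        labels[pos, task_idx] = 1
        graph = featurize_chain(chain, cfg, providers)
        offset = signal_scale * np.ones(signal_dims)
        graph.node_features[pos, :signal_dims] += offset
        mask = np.ones_like(labels, dtype=float)
        examples.append(TrainingExample(chain_id=f"chain{k}", graph=graph,
                                        labels=labels, mask=mask))
    return examples
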
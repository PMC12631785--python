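"""Node feature blocks and their assembly into the L x 2247 matrix."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np

from .common import VIRTUAL_ATOM_ORDER, FeaturizationError, rbf_encode
from .dssp import DSSP_DIM, dssp_features

#: default block layout; the concatenation order is fixed
DEFAULT_NODE_BLOCKS = {
    "prottrans": 1024,
    "prostt5_aa": 1024,
    "dssp": DSSP_DIM,
    "geometric_residue": 160,
    "atomic_residue": 30,
}

GEOMETRIC_PAIRS = tuple(combinations(VIRTUAL_ATOM_ORDER, 2))  # 10 unordered pairs

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: aromatic ring atoms per residue type
_AROMATIC_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

#: crude formal-charge proxies for ionisable side-chain atoms
_CHARGE_PROXY = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5, ("ARG", "NE"): 0.0,
    ("HIS", "ND1"): 0.25, ("HIS", "NE2"): 0.25,
}

_ELEMENT_ONEHOT = ("C", "N", "O", "S")  # + "other" slot
ATOM_DESCRIPTOR_DIM = 15


def _load_atom_properties() -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    with resources.as_file(resources.files("mpbind.data") / "atom_properties.tsv") as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                el = row.pop("element")
                table[el] = {k: float(v) for k, v in row.items()}
    return table


_ATOM_PROPS = _load_atom_properties()


@dataclass
class NodeFeatureConfig:
    """Enabled node blocks with dimensions; default totals 2247."""

    blocks: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_NODE_BLOCKS))

    @property
    def total(self) -> int:
        return sum(self.blocks.values())

    def offsets(self) -> dict[str, tuple[int, int]]:
        out, start = {}, 0
        for name, dim in self.blocks.items():
            out[name] = (start, start + dim)
            start += dim
        return out

    def without(self, *names: str) -> "NodeFeatureConfig":
        return NodeFeatureConfig({k: v for k, v in self.blocks.items() if k not in names})


def geometric_residue_features(residue, frame=None) -> np.ndarray:
    """160-vector: RBF encodings of the 10 virtual-atom pair distances."""
    va = residue.virtual_atoms
    if va is None:
        raise FeaturizationError(
            f"residue {residue.comp_id}{residue.author_number} lacks virtual atoms"
        )
    dists = np.array([np.linalg.norm(va[a] - va[b]) for a, b in GEOMETRIC_PAIRS])
    return rbf_encode(dists).ravel()


def atom_descriptors(residue, atom) -> np.ndarray:
    """The 15 per-atom descriptors pooled by :func:`atomic_residue_features`."""
    el = atom.element.upper()
    props = _ATOM_PROPS.get(el, _ATOM_PROPS["X"])
    onehot = [1.0 if el == e else 0.0 for e in _ELEMENT_ONEHOT]
    onehot.append(1.0 if el not in _ELEMENT_ONEHOT else 0.0)
    charge = _CHARGE_PROXY.get((residue.comp_id, atom.name), 0.0)
    aromatic = 1.0 if atom.name in _AROMATIC_ATOMS.get(residue.comp_id, ()) else 0.0
    backbone = 1.0 if atom.name in _BACKBONE_NAMES else 0.0
    return np.array(
        onehot
        + [charge, props["mass"], props["vdw_radius"], aromatic, backbone,
           props["electronegativity"], props["covalent_radius"],
           props["polarizability"], props["hb_donor"], props["hb_acceptor"]]
    )


def atomic_residue_features(residue) -> np.ndarray:
    """30-vector: mean pool and sum pool of the per-atom descriptors."""
    heavy = residue.heavy_atoms
    if not heavy:
        raise FeaturizationError(
            f"residue {residue.comp_id}{residue.author_number} has no heavy atoms"
        )
    desc = np.stack([atom_descriptors(residue, a) for a in heavy])
    return np.concatenate([desc.mean(axis=0), desc.sum(axis=0)])


def assemble_node_features(chain, cfg: NodeFeatureConfig, providers: dict) -> np.ndarray:
    """Concatenate enabled blocks in config order into the (L, total) matrix."""
    from ..structure_io import extract_sequence

    L = len(chain)
    parts: list[np.ndarray] = []
    sequence = extract_sequence(chain)
    for name, dim in cfg.blocks.items():
        if name in ("prottrans", "prostt5_aa", "prostt5_3di"):
            provider = providers.get(name)
            if provider is None:
                raise FeaturizationError(f"no embedding provider for block {name!r}")
            block = np.asarray(provider.embed(sequence), dtype=float)
        elif name == "dssp":
            block = dssp_features(chain)
        elif name == "geometric_residue":
            block = np.stack([geometric_residue_features(r) for r in chain.residues])
        elif name == "atomic_residue":
            block = np.stack([atomic_residue_features(r) for r in chain.residues])
        else:
            raise FeaturizationError(f"unknown node feature block {name!r}")
        if block.shape != (L, dim):
            raise FeaturizationError(
                f"block {name!r}: shape {block.shape} != ({L}, {dim})"
            )
        parts.append(block)
    out = np.concatenate(parts, axis=1)
    assert out.shape == (L, cfg.total)
    return out
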
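"""Structure parsing, preprocessing and entity classification.

Reads mmCIF/legacy PDB files (first model only), strips hydrogen/deuterium
atoms, water/heavy water and alternate locations (first occurrence in file
order wins), and classifies every remaining entity against the molecule
registry: polymer chains of amino acids become :class:`Chain` objects, every
other registered component becomes a :class:`PartnerEntity`. Unregistered
hetero components are kept as inert context and reported, never silently
dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx

from .registry import MoleculeRegistry

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
VIRTUAL_ATOM_KEYS = ("N", "C", "CA", "O", "R")

#: three-letter to one-letter translation; non-standard entries are the
#: decision table for sequence extraction (parent standard residue).
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # decision table for common non-standard residues
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}

STANDARD_AA3 = tuple(sorted(k for k, v in AA3_TO_1.items()))

#: canonical interface-matrix row order: alphabetical one-letter codes
AA_ROW_ORDER = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

WATER_COMP_IDS = frozenset({"HOH", "DOD"})
_HYDROGEN_ELEMENTS = frozenset({"H", "D"})

_NUCLEOTIDE_COMPS = frozenset({"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"})


class StructureError(ValueError):
    pass


class ParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


@dataclass
class Atom:
    """A heavy (or, pre-preprocessing, any) atom."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise StructureError(f"atom {self.name!r} has empty element")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r} has non-finite coordinates")


@dataclass
class Residue:
    comp_id: str
    one_letter: str
    author_number: str
    index: int
    atoms: list[Atom] = field(default_factory=list)
    virtual_atoms: dict[str, np.ndarray] | None = None
    incomplete: bool = False
    hetero: bool = False

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element not in _HYDROGEN_ELEMENTS]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def heavy_atom_count(self) -> int:
        return sum(len(r.heavy_atoms) for r in self.residues)


@dataclass
class PartnerEntity:
    """A registered non-target entity: a foreign residue group, nucleic chain,
    or a single ion/ligand/lipid monomer."""

    category: str
    comp_id: str
    atoms: list[Atom]
    chain_id: str = ""
    label: str = ""

    @property
    def size(self) -> int:
        return len(self.atoms)


@dataclass
class ComplexStructure:
    chains: list[Chain] = field(default_factory=list)
    partners: list[PartnerEntity] = field(default_factory=list)
    source_id: str = ""
    #: unregistered hetero entities kept as inert context (never labeled)
    context: list[PartnerEntity] = field(default_factory=list)
    classified: bool = False

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.source_id!r}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _atom_array_to_structure(arr: struc.AtomArray, source_id: str) -> ComplexStructure:
    if arr.array_length() == 0:
        raise EmptyStructureError(f"{source_id}: no atoms in first model")
    if "altloc_id" in arr.get_annotation_categories():
        altlocs = arr.altloc_id
    else:
        altlocs = np.full(arr.array_length(), "", dtype="U1")
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else np.full(
        arr.array_length(), "", dtype="U1"
    )

    chains: dict[str, Chain] = {}
    res_key_to_residue: dict[tuple, Residue] = {}
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        key = (cid, int(arr.res_id[i]), str(ins[i]), str(arr.res_name[i]))
        if key not in res_key_to_residue:
            chain = chains.setdefault(cid, Chain(chain_id=cid))
            comp = str(arr.res_name[i])
            res = Residue(
                comp_id=comp,
                one_letter=AA3_TO_1.get(comp, "X"),
                author_number=f"{int(arr.res_id[i])}{str(ins[i]).strip()}",
                index=len(chain.residues),
                hetero=bool(arr.hetero[i]),
            )
            chain.residues.append(res)
            res_key_to_residue[key] = res
        alt = str(altlocs[i]).strip().replace(".", "")
        res_key_to_residue[key].atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper(),
                coords=np.asarray(arr.coord[i], dtype=float),
                altloc=alt,
            )
        )
    return ComplexStructure(chains=list(chains.values()), source_id=source_id)


def parse_structure(path: str | Path, format: str | None = None) -> ComplexStructure:
    """Parse an mmCIF or PDB file into a raw (unpreprocessed) structure.

    Only the first model is read; altloc copies are preserved verbatim so
    that :func:`preprocess` can apply the first-occurrence rule.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif"
    if format not in {"mmcif", "pdb"}:
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "mmcif":
                cif = _pdbx.CIFFile.read(str(path))
                arr = _pdbx.get_structure(cif, model=1, altloc="all")
            else:
                pdbf = _pdb.PDBFile.read(str(path))
                arr = pdbf.get_structure(model=1, altloc="all")
    except (EmptyStructureError, StructureError):
        raise
    except Exception as exc:  # parser-level failure: re-raise with context
        raise ParseError(f"{path}: failed to parse as {format}: {exc}") from exc
    return _atom_array_to_structure(arr, source_id=path.stem)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw: ComplexStructure) -> ComplexStructure:
    """Apply the cleaning rules: drop H/D atoms, water/heavy-water residues,
    and all but the first-occurring altloc of each atom position.

    Idempotent; returns a new structure and leaves the input untouched.
    """
    chains: list[Chain] = []
    for chain in raw.chains:
        new_residues: list[Residue] = []
        for res in chain.residues:
            if res.comp_id in WATER_COMP_IDS:
                continue
            seen_names: set[str] = set()
            kept: list[Atom] = []
            for atom in res.atoms:
                if atom.element in _HYDROGEN_ELEMENTS:
                    continue
                if atom.name in seen_names:
                    continue  # later altloc of an already-seen position
                seen_names.add(atom.name)
                kept.append(Atom(atom.name, atom.element, atom.coords.copy(), atom.altloc))
            if not kept:
                continue
            new_residues.append(
                Residue(
                    comp_id=res.comp_id,
                    one_letter=res.one_letter,
                    author_number=res.author_number,
                    index=len(new_residues),
                    atoms=kept,
                    hetero=res.hetero,
                )
            )
        if new_residues:
            chains.append(Chain(chain_id=chain.chain_id, residues=new_residues))
    if not chains:
        raise EmptyStructureError(f"{raw.source_id}: nothing left after preprocessing")
    return ComplexStructure(chains=chains, source_id=raw.source_id)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_STANDARD_AA3 = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})


def _is_amino(res: Residue) -> bool:
    # hetero-flagged residues of a *standard* comp (e.g. a free ALA ligand)
    # are crystallization context; hetero non-standard comps (e.g. MSE) are
    # polymer residues written as HETATM records
    if res.comp_id not in AA3_TO_1:
        return False
    return not res.hetero or res.comp_id not in _STANDARD_AA3


def _is_nucleotide(res: Residue, reg: MoleculeRegistry) -> bool:
    return res.comp_id in _NUCLEOTIDE_COMPS and reg.category(res.comp_id) == "nucleotide"


def classify_entities(s: ComplexStructure, reg: MoleculeRegistry) -> ComplexStructure:
    """Split a preprocessed structure into protein chains and partner entities.

    Amino-acid polymer residues form :class:`Chain` objects (with virtual
    atoms computed); nucleotide polymer residues are grouped into one
    partner entity per chain; registered ions/ligands/lipids become one
    partner entity per monomer. Unregistered components go to ``context``.
    """
    chains: list[Chain] = []
    partners: list[PartnerEntity] = []
    context: list[PartnerEntity] = []
    for chain in s.chains:
        aa_residues = [r for r in chain.residues if _is_amino(r)]
        nuc_residues = [r for r in chain.residues if _is_nucleotide(r, reg)]
        other = [
            r for r in chain.residues
            if not _is_amino(r) and not _is_nucleotide(r, reg)
        ]
        if aa_residues:
            new_chain = Chain(chain_id=chain.chain_id)
            for r in aa_residues:
                rr = Residue(
                    comp_id=r.comp_id,
                    one_letter=r.one_letter,
                    author_number=r.author_number,
                    index=len(new_chain.residues),
                    atoms=list(r.atoms),
                    hetero=r.hetero,
                )
                compute_virtual_atoms(rr)
                new_chain.residues.append(rr)
            chains.append(new_chain)
        if nuc_residues:
            atoms = [a for r in nuc_residues for a in r.atoms]
            partners.append(
                PartnerEntity(
                    category="nucleotide",
                    comp_id=nuc_residues[0].comp_id,
                    atoms=atoms,
                    chain_id=chain.chain_id,
                    label=f"{chain.chain_id}/nucleic",
                )
            )
        for r in other:
            cat = reg.category(r.comp_id)
            ent = PartnerEntity(
                category=cat if cat is not None else "unregistered",
                comp_id=r.comp_id,
                atoms=list(r.atoms),
                chain_id=chain.chain_id,
                label=f"{chain.chain_id}/{r.comp_id}{r.author_number}",
            )
            if cat is None or cat == "amino_acid":
                # free amino-acid monomers and unknown hetero components are
                # inert context, mirroring the exclusion of crystallization aids
                logger.info(
                    "%s: unregistered entity %s kept as context", s.source_id, ent.label
                )
                context.append(ent)
            else:
                partners.append(ent)
    return ComplexStructure(
        chains=chains,
        partners=partners,
        context=context,
        source_id=s.source_id,
        classified=True,
    )


# ---------------------------------------------------------------------------
# virtual atoms & sequence
# ---------------------------------------------------------------------------

def compute_virtual_atoms(r: Residue) -> Residue:
    """Populate the five virtual atoms {N, C, CA, O, R} in place.

    R is the unweighted centroid of side-chain heavy atoms; glycine (or any
    residue without side-chain heavy atoms) falls back to R = CA. Residues
    missing a backbone atom are flagged ``incomplete`` and get no virtual
    atoms.
    """
    backbone = {}
    for name in BACKBONE_ATOMS:
        a = r.atom(name)
        if a is None or a.element in _HYDROGEN_ELEMENTS:
            r.incomplete = True
            r.virtual_atoms = None
            return r
        backbone[name] = a.coords.astype(float)
    side = [
        a.coords
        for a in r.heavy_atoms
        if a.name not in ("N", "CA", "C", "O", "OXT")
    ]
    rc = np.mean(side, axis=0) if side else backbone["CA"].copy()
    r.virtual_atoms = {
        "N": backbone["N"],
        "C": backbone["C"],
        "CA": backbone["CA"],
        "O": backbone["O"],
        "R": np.asarray(rc, dtype=float),
    }
    r.incomplete = False
    return r


def extract_sequence(c: Chain) -> str:
    """One-letter sequence of a classified chain ('X' for unknown residues)."""
    return "".join(res.one_letter for res in c.residues)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _structure_to_atom_array(s: ComplexStructure) -> struc.AtomArray:
    rows: list[tuple] = []
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                rows.append((chain.chain_id, res, a, res.hetero))
    for ent in list(s.partners) + list(s.context):
        cid = ent.chain_id or "Z"
        for a in ent.atoms:
            pseudo = Residue(ent.comp_id, "X", "1", 0, hetero=True)
            rows.append((cid, pseudo, a, True))
    arr = struc.AtomArray(len(rows))
    for i, (cid, res, a, het) in enumerate(rows):
        num = res.author_number
        digits = "".join(ch for ch in num if ch.isdigit() or ch == "-") or "1"
        arr.chain_id[i] = cid
        arr.res_id[i] = int(digits)
        arr.ins_code[i] = "".join(ch for ch in num if ch.isalpha())
        arr.res_name[i] = res.comp_id
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = het
        arr.coord[i] = a.coords
    return arr


def write_structure(s: ComplexStructure, path: str | Path) -> None:
    """Write a structure as mmCIF."""
    arr = _structure_to_atom_array(s)
    cif = _pdbx.CIFFile()
    _pdbx.set_structure(cif, arr, data_block=s.source_id or "structure")
    cif.write(str(path))
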
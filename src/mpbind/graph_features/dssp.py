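"""Secondary structure (Kabsch-Sander hydrogen bonds) and solvent accessibility.

Internal implementation of the classic assignment: amide hydrogens are
placed 1 A from N along the previous residue's O->C direction, hydrogen-bond
energy is the Kabsch-Sander electrostatic form, and 8 states
(H, B, E, G, I, T, S, '-') are assigned from n-turn and bridge patterns.
Relative solvent accessibility comes from Shrake-Rupley areas normalised by
per-residue maxima. An external DSSP table can be ingested instead.
"""

from __future__ import annotations

import warnings

import numpy as np

from .common import FeaturizationError

SS_STATES = ("H", "B", "E", "G", "I", "T", "S", "-")
DSSP_DIM = len(SS_STATES) + 1  # 8-state one-hot + RSA

_KS_Q1Q2_F = 0.084 * 332.0
_HBOND_ENERGY_CUTOFF = -0.5

#: Tien et al. (2013) theoretical maximum accessible surface areas (A^2)
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}


def _backbone_arrays(chain) -> dict[str, np.ndarray]:
    out = {name: np.full((len(chain), 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(chain.residues):
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            if a is None:
                raise FeaturizationError(
                    f"residue {res.comp_id}{res.author_number} misses backbone atom {name}"
                )
            out[name][i] = a.coords
    return out


def hbond_matrix(chain) -> np.ndarray:
    """Boolean (L, L): entry [i, j] means N-H of i donates to C=O of j."""
    bb = _backbone_arrays(chain)
    L = len(chain)
    n, ca, c, o = bb["N"], bb["CA"], bb["C"], bb["O"]
    # amide H: 1 A from N, parallel to previous residue's O->C vector
    h = np.full((L, 3), np.nan)
    vec = c[:-1] - o[:-1]
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    h[1:] = n[1:] + vec

    hb = np.zeros((L, L), dtype=bool)
    if L < 2:
        return hb

    def dist(a, b):
        return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))

    with np.errstate(invalid="ignore", divide="ignore"):
        r_on = dist(o, n)   # [j, i] -> use transposed indexing below
        r_ch = dist(c, h)
        r_oh = dist(o, h)
        r_cn = dist(c, n)
        # E for donor i, acceptor j
        energy = _KS_Q1Q2_F * (1.0 / r_on.T + 1.0 / r_ch.T - 1.0 / r_oh.T - 1.0 / r_cn.T)
    idx = np.arange(L)
    energy[np.isnan(energy)] = 0.0
    energy[idx, idx] = 0.0
    # no bond between direct sequence neighbours
    for k in (1,):
        energy[idx[:-k], idx[k:]] = 0.0
        energy[idx[k:], idx[:-k]] = 0.0
    hb = energy < _HBOND_ENERGY_CUTOFF
    hb[0, :] = False  # first residue has no amide H
    return hb


def assign_secondary_structure(chain) -> list[str]:
    """8-state assignment per residue."""
    L = len(chain)
    if L < 4:
        return ["-"] * L
    hb = hbond_matrix(chain)

    def turn(n_):
        t = np.zeros(L, dtype=bool)
        for i in range(L - n_):
            if hb[i + n_, i]:
                t[i] = True
        return t

    t3, t4, t5 = turn(3), turn(4), turn(5)

    def helix(tn, n_):
        flags = np.zeros(L, dtype=bool)
        for i in range(1, L - n_):
            if tn[i - 1] and tn[i]:
                flags[i:i + n_] = True
        return flags

    h4 = helix(t4, 4)
    h3 = helix(t3, 3)
    h5 = helix(t5, 5)

    # bridges
    bridge = np.zeros(L, dtype=bool)
    ladder = np.zeros(L, dtype=bool)
    partners: dict[int, list[int]] = {}
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (hb[i, j - 1] and hb[j + 1, i]) or (hb[j, i - 1] and hb[i + 1, j])
            anti = (hb[i, j] and hb[j, i]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                partners.setdefault(i, []).append(j)
                partners.setdefault(j, []).append(i)
                bridge[i] = bridge[j] = True
    # ladders: consecutive bridge residues with consecutive partners
    for i in list(partners):
        for j in partners[i]:
            if (i + 1 in partners) and any(abs(j2 - j) == 1 for j2 in partners[i + 1]):
                ladder[i] = ladder[i + 1] = True
                ladder[j] = True

    # turns (T): residues inside an n-turn
    t_flag = np.zeros(L, dtype=bool)
    for n_, tn in ((3, t3), (4, t4), (5, t5)):
        for i in range(L - n_):
            if tn[i]:
                t_flag[i + 1:i + n_] = True

    # bend (S): kappa > 70 degrees
    bb = _backbone_arrays(chain)
    ca = bb["CA"]
    s_flag = np.zeros(L, dtype=bool)
    for i in range(2, L - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            s_flag[i] = True

    ss = []
    for i in range(L):
        if h4[i]:
            ss.append("H")
        elif ladder[i]:
            ss.append("E")
        elif bridge[i]:
            ss.append("B")
        elif h3[i]:
            ss.append("G")
        elif h5[i]:
            ss.append("I")
        elif t_flag[i]:
            ss.append("T")
        elif s_flag[i]:
            ss.append("S")
        else:
            ss.append("-")
    return ss


def _canonical_transform(chain) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform into the first complete residue's backbone frame, so
    that point-sampled surface areas are invariant to global rigid motions."""
    for res in chain.residues:
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if n is None or ca is None or c is None:
            continue
        z = np.cross(n.coords - ca.coords, c.coords - ca.coords)
        nz = np.linalg.norm(z)
        if nz < 1e-8:
            continue
        z = z / nz
        x = c.coords - n.coords
        x = x - np.dot(x, z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        basis = np.stack([x, y, z], axis=1)
        return basis.T, ca.coords
    return np.eye(3), np.zeros(3)


def relative_accessibility(chain) -> np.ndarray:
    """Per-residue RSA in [0, 1] via Shrake-Rupley SASA (biotite)."""
    import biotite.structure as struc

    rot, origin = _canonical_transform(chain)
    atoms = [(res, a) for res in chain.residues for a in res.heavy_atoms]
    arr = struc.AtomArray(len(atoms))
    for k, (res, a) in enumerate(atoms):
        arr.chain_id[k] = chain.chain_id or "A"
        arr.res_id[k] = res.index + 1
        arr.res_name[k] = res.comp_id
        arr.atom_name[k] = a.name
        arr.element[k] = a.element if len(a.element) <= 2 else a.element[:2]
        arr.coord[k] = rot @ (a.coords - origin)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sasa = struc.sasa(arr, point_number=100)
    sasa = np.nan_to_num(sasa, nan=0.0)
    rsa = np.zeros(len(chain))
    for k, (res, _) in enumerate(atoms):
        rsa[res.index] += sasa[k]
    for res in chain.residues:
        rsa[res.index] /= MAX_ASA.get(res.one_letter, MAX_ASA["X"])
    return np.clip(rsa, 0.0, 1.0)


def dssp_features(chain, external: list[tuple[str, float]] | None = None) -> np.ndarray:
    """(L, 9) matrix: 8-state one-hot + RSA.

    ``external`` optionally supplies per-residue (state, rsa) pairs from a
    reference DSSP run, bypassing the internal implementation.
    """
    L = len(chain)
    if external is not None:
        if len(external) != L:
            raise FeaturizationError("external DSSP length mismatch")
        states = [s if s in SS_STATES else "-" for s, _ in external]
        rsa = np.clip([r for _, r in external], 0.0, 1.0)
    else:
        states = assign_secondary_structure(chain)
        rsa = relative_accessibility(chain)
    out = np.zeros((L, DSSP_DIM))
    for i, s in enumerate(states):
        out[i, SS_STATES.index(s)] = 1.0
    out[:, -1] = rsa
    return out
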
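"""Synthetic molecule fixtures with idealized geometry.

Desk-scale stand-ins for a benchmark set of small organics (H/C/N/O/F,
few heavy atoms, 3D coordinates, formal charges, explicit bond orders).
Every set is deterministic given its seed; geometries use idealized bond
lengths and angles so geometry metrics have known ground truth.  The
``invalid_valence`` and ``disconnected`` sets deliberately violate the
valence rules / connectivity so the metric suite has negative controls.
"""

from __future__ import annotations

import numpy as np

from .molgraph import DEFAULT_VOCAB, Molecule3DGraph, center_com

__all__ = ["generate_fixtures", "FIXTURE_SETS"]

# idealized bond lengths, Å
CC = 1.54
CC_DOUBLE = 1.33
CH = 1.09
OH = 0.96
NH = 1.01
TET = np.degrees(np.arccos(-1 / 3))  # 109.471...


def _mol(symbols, coords, bonds_list, charges=None, mol_id="", jitter=0.0, rng=None):
    vocab = DEFAULT_VOCAB
    n = len(symbols)
    types = np.array([vocab.atom_index(s) for s in symbols])
    q = np.full(n, vocab.charge_index(0)) if charges is None else np.array(
        [vocab.charge_index(c) for c in charges]
    )
    bonds = np.zeros((n, n), dtype=np.int64)
    order_idx = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}
    for i, j, order in bonds_list:
        bonds[i, j] = bonds[j, i] = order_idx[order]
    coords = np.asarray(coords, dtype=np.float64)
    if jitter > 0:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    return Molecule3DGraph(center_com(coords), types, q, bonds, id=mol_id, vocab=vocab)


def _tetrahedral_dirs() -> np.ndarray:
    d = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return d / np.sqrt(3)


def methane(**kw) -> Molecule3DGraph:
    coords = [[0.0, 0.0, 0.0]] + list(CH * _tetrahedral_dirs())
    bonds = [(0, i, "single") for i in range(1, 5)]
    return _mol(["C", "H", "H", "H", "H"], coords, bonds, mol_id="methane", **kw)


def water(**kw) -> Molecule3DGraph:
    half = np.radians(104.5 / 2)
    coords = [
        [0.0, 0.0, 0.0],
        [OH * np.sin(half), OH * np.cos(half), 0.0],
        [-OH * np.sin(half), OH * np.cos(half), 0.0],
    ]
    return _mol(["O", "H", "H"], coords, [(0, 1, "single"), (0, 2, "single")], mol_id="water", **kw)


def ammonia(**kw) -> Molecule3DGraph:
    # three N-H bonds at 107 degrees to each other, symmetric about z
    cos_t = np.sqrt((2 * np.cos(np.radians(107)) + 1) / 3)
    sin_t = np.sqrt(1 - cos_t**2)
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        a = 2 * np.pi * k / 3
        coords.append([NH * sin_t * np.cos(a), NH * sin_t * np.sin(a), -NH * cos_t])
    bonds = [(0, i, "single") for i in range(1, 4)]
    return _mol(["N", "H", "H", "H"], coords, bonds, mol_id="ammonia", **kw)


def _staggered_ethane_coords() -> np.ndarray:
    half = CC / 2
    cos_t = 1 / 3  # cos(180 - 109.47) relative to C-C axis
    sin_t = np.sqrt(1 - cos_t**2)
    coords = [[0.0, 0.0, half], [0.0, 0.0, -half]]
    for k in range(3):  # H on top carbon
        a = 2 * np.pi * k / 3
        coords.append([CH * sin_t * np.cos(a), CH * sin_t * np.sin(a), half + CH * cos_t])
    for k in range(3):  # staggered H on bottom carbon
        a = 2 * np.pi * k / 3 + np.pi / 3
        coords.append([CH * sin_t * np.cos(a), CH * sin_t * np.sin(a), -half - CH * cos_t])
    return np.array(coords)


def ethane(**kw) -> Molecule3DGraph:
    bonds = [(0, 1, "single")]
    bonds += [(0, i, "single") for i in (2, 3, 4)]
    bonds += [(1, i, "single") for i in (5, 6, 7)]
    return _mol(["C", "C"] + ["H"] * 6, _staggered_ethane_coords(), bonds, mol_id="ethane", **kw)


def ethene(**kw) -> Molecule3DGraph:
    half = CC_DOUBLE / 2
    a = np.radians(60)  # H-C-C angle 120 deg, planar
    coords = [
        [half, 0.0, 0.0],
        [-half, 0.0, 0.0],
        [half + CH * np.sin(a), CH * np.cos(a), 0.0],
        [half + CH * np.sin(a), -CH * np.cos(a), 0.0],
        [-half - CH * np.sin(a), CH * np.cos(a), 0.0],
        [-half - CH * np.sin(a), -CH * np.cos(a), 0.0],
    ]
    bonds = [(0, 1, "double"), (0, 2, "single"), (0, 3, "single"), (1, 4, "single"), (1, 5, "single")]
    return _mol(["C", "C"] + ["H"] * 4, coords, bonds, mol_id="ethene", **kw)


def _alkane(k: int, mol_id: str = "", **kw) -> Molecule3DGraph:
    """Linear alkane C_k H_{2k+2} in an ideal zigzag conformation."""
    if k < 1:
        raise ValueError("chain length must be >= 1")
    if k == 1:
        m = methane(**kw)
        m.id = mol_id or "chain1"
        return m
    theta = np.radians(TET)
    dx = CC * np.sin(theta / 2)
    dz = CC * np.cos(theta / 2)
    carbons = np.array([[i * dx, 0.0, (i % 2) * dz] for i in range(k)])
    symbols = ["C"] * k
    coords = list(carbons)
    bonds = [(i, i + 1, "single") for i in range(k - 1)]

    def remaining_tet_dirs(u1, u2):
        # the two unit vectors completing a tetrahedral arrangement with u1, u2
        c = np.cross(u1, u2)
        c = c / np.linalg.norm(c)
        base = -(u1 + u2) / 2
        return base + (np.sqrt(3) / 2) * np.sqrt(8) / 3 * c, base - (np.sqrt(3) / 2) * np.sqrt(8) / 3 * c

    def norm(v):
        return v / np.linalg.norm(v)

    for i in range(k):
        nbrs = []
        if i > 0:
            nbrs.append(norm(carbons[i - 1] - carbons[i]))
        if i < k - 1:
            nbrs.append(norm(carbons[i + 1] - carbons[i]))
        if len(nbrs) == 2:
            d1, d2 = remaining_tet_dirs(nbrs[0], nbrs[1])
            h_dirs = [norm(d1), norm(d2)]
        else:
            # terminal carbon: tripod of three directions around -u1
            u1 = nbrs[0]
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(ref, u1)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = norm(np.cross(u1, ref))
            e2 = np.cross(u1, e1)
            cos_t, sin_t = -1 / 3, np.sqrt(8) / 3
            h_dirs = [
                norm(cos_t * u1 + sin_t * (np.cos(a) * e1 + np.sin(a) * e2))
                for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
            ]
        for d in h_dirs:
            symbols.append("H")
            coords.append(carbons[i] + CH * d)
            bonds.append((i, len(coords) - 1, "single"))
    return _mol(symbols, coords, bonds, mol_id=mol_id or f"chain{k}", **kw)


def _invalid_valence_set(**kw) -> list[Molecule3DGraph]:
    """A pentavalent-carbon methane: exactly one valence violation."""
    base = methane(**kw)
    n = base.n_atoms + 1
    coords = np.vstack([base.coords, [[0.0, 0.0, CH]]])
    types = np.append(base.atom_types, base.vocab.atom_index("H"))
    charges = np.append(base.charges, base.vocab.charge_index(0))
    bonds = np.zeros((n, n), dtype=np.int64)
    bonds[: n - 1, : n - 1] = base.bonds
    c_idx = 0
    bonds[c_idx, n - 1] = bonds[n - 1, c_idx] = 1
    return [
        Molecule3DGraph(center_com(coords), types, charges, bonds, id="pentavalent_methane")
    ]


def _disconnected_set(**kw) -> list[Molecule3DGraph]:
    """Two methane fragments in one record; bond graph has 2 components."""
    a = methane(**kw)
    n = 2 * a.n_atoms
    coords = np.vstack([a.coords, a.coords + np.array([6.0, 0.0, 0.0])])
    types = np.concatenate([a.atom_types, a.atom_types])
    charges = np.concatenate([a.charges, a.charges])
    bonds = np.zeros((n, n), dtype=np.int64)
    bonds[: a.n_atoms, : a.n_atoms] = a.bonds
    bonds[a.n_atoms :, a.n_atoms :] = a.bonds
    return [
        Molecule3DGraph(center_com(coords), types, charges, bonds, id="two_methanes")
    ]


FIXTURE_SETS = ("minimal", "chains", "invalid_valence", "disconnected")


def generate_fixtures(
    name: str, seed: int = 0, k: int = 5, jitter: float = 0.0
) -> list[Molecule3DGraph]:
    """Generate a named fixture set.

    Parameters
    ----------
    name : one of "minimal" (methane/water/ammonia/ethane/ethene, all valid
        and connected), "chains" (k linear alkanes from propane up,
        disjoint from "minimal"), "invalid_valence" (one pentavalent
        carbon), "disconnected" (two fragments).
    seed : seeds the coordinate jitter; with jitter=0 (default) geometry is
        exactly idealized and the seed has no effect.
    k : chain count for "chains".
    jitter : Gaussian coordinate noise in Å added to the ideal geometry.
    """
    rng = np.random.default_rng(seed)
    kw = {"jitter": jitter, "rng": rng}
    if name == "minimal":
        return [methane(**kw), water(**kw), ammonia(**kw), ethane(**kw), ethene(**kw)]
    if name == "chains":
        # start at propane so the set is disjoint from "minimal"
        return [_alkane(i, **kw) for i in range(3, k + 3)]
    if name == "invalid_valence":
        return _invalid_valence_set(**kw)
    if name == "disconnected":
        return _disconnected_set(**kw)
    raise ValueError(f"unknown fixture set {name!r}; expected one of {FIXTURE_SETS}")
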
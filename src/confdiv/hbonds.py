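"""Geometric intra-protein hydrogen-bond counting.

Backbone amide hydrogens are placed geometrically (1 Å from N, anti to the
preceding carbonyl); a backbone donor–acceptor contact counts when
D–A ≤ 3.9 Å, H–A ≤ 2.5 Å and the D-H-A angle is ≥ 90°. Side-chain donors
carry no modeled hydrogens, so they are scored on heavy atoms only:
D–A ≤ 3.5 Å with the angle at the donor (antecedent-D-A) ≥ 90°. Waters and
HET groups never participate. Absolute counts therefore differ from
hydrogen-resolved tools; differences between conformers are the analysis
surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import ResKey, Structure

D_A_MAX = 3.9       # Å, backbone donor-acceptor
H_A_MAX = 2.5       # Å, hydrogen-acceptor
SC_D_A_MAX = 3.5    # Å, side-chain donor-acceptor (heavy-atom criterion)
ANGLE_MIN = 90.0    # degrees

# side-chain donor atoms and their antecedent (for the angle test)
_SC_DONORS = {
    ("ARG", "NE"): "CD", ("ARG", "NH1"): "CZ", ("ARG", "NH2"): "CZ",
    ("LYS", "NZ"): "CE", ("HIS", "ND1"): "CG", ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1", ("ASN", "ND2"): "CG", ("GLN", "NE2"): "CD",
    ("SER", "OG"): "CB", ("THR", "OG1"): "CB", ("TYR", "OH"): "CZ",
    ("CYS", "SG"): "CB",
}
# side-chain acceptor atoms
_SC_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}


@dataclass
class _Donor:
    coords: np.ndarray
    h_coords: np.ndarray | None   # None → heavy-atom criteria
    antecedent: np.ndarray | None
    res_key: ResKey
    backbone: bool


@dataclass
class _Acceptor:
    coords: np.ndarray
    res_key: ResKey
    backbone: bool
    seq_index: tuple[str, int]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def list_hbonds(structure: Structure) -> list[tuple[ResKey, ResKey]]:
    """All intra-protein donor→acceptor contacts meeting the criteria."""
    donors: list[_Donor] = []
    acceptors: list[_Acceptor] = []
    for chain_id in structure.chains:
        residues = structure.polymer_residues(chain_id)
        for i, r in enumerate(residues):
            n_at, ca, c_at, o_at = (r.atom(x) for x in ("N", "CA", "C", "O"))
            prev = residues[i - 1] if i > 0 else None
            contiguous = prev is not None and prev.seq_num == r.seq_num - 1
            if n_at is not None and r.res_name != "PRO":
                h = None
                if contiguous and prev.atom("C") is not None and prev.atom("O") is not None:
                    d = prev.atom("C").coords - prev.atom("O").coords
                    h = n_at.coords + d / np.linalg.norm(d)
                if h is not None:
                    donors.append(_Donor(n_at.coords, h, None, r.key, True))
            if o_at is not None and c_at is not None:
                acceptors.append(_Acceptor(o_at.coords, r.key, True,
                                           (chain_id, r.seq_num)))
            for (res_name, atom_name), antecedent in _SC_DONORS.items():
                if r.res_name == res_name and r.atom(atom_name) is not None:
                    ant = r.atom(antecedent)
                    donors.append(_Donor(r.atom(atom_name).coords, None,
                                         ant.coords if ant else None, r.key, False))
            for res_name, atom_name in _SC_ACCEPTORS:
                if r.res_name == res_name and r.atom(atom_name) is not None:
                    acceptors.append(_Acceptor(r.atom(atom_name).coords, r.key,
                                               False, (chain_id, r.seq_num)))
    if not donors or not acceptors:
        return []

    acc_coords = np.array([a.coords for a in acceptors])
    tree = cKDTree(acc_coords)
    bonds: list[tuple[ResKey, ResKey]] = []
    for d in donors:
        cutoff = D_A_MAX if d.backbone else SC_D_A_MAX
        for j in tree.query_ball_point(d.coords, cutoff):
            acc = acceptors[j]
            if acc.res_key == d.res_key:
                continue
            # donor N(i) and acceptor O(i-1) are covalent neighbors
            if (d.backbone and acc.backbone
                    and acc.seq_index == (d.res_key[0], d.res_key[1] - 1)):
                continue
            if d.h_coords is not None:
                if np.linalg.norm(acc.coords - d.h_coords) > H_A_MAX:
                    continue
                if _angle(d.coords, d.h_coords, acc.coords) < ANGLE_MIN:
                    continue
            else:
                if d.antecedent is not None and _angle(
                        d.antecedent, d.coords, acc.coords) < ANGLE_MIN:
                    continue
            bonds.append((d.res_key, acc.res_key))
    return bonds


def count_hbonds(structure: Structure) -> int:
    """Number of intra-protein hydrogen bonds under the geometric criteria."""
    return len(list_hbonds(structure))
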
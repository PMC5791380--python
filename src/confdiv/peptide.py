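"""Ideal-geometry peptide backbone construction.

Backbone atoms (N, Cα, C, O, plus Cβ for non-glycine) are placed from
internal coordinates by sequential natural extension (NeRF): each atom is
positioned from a bond length, a bond angle and a torsion relative to the
three previously placed atoms. Bond lengths and angles are the standard
Engh–Huber-style ideal values; φ/ψ are supplied per residue, ω is trans.

This is the geometric core shared by the synthetic-conformer generator and
the ALA-X-ALA reference-tripeptide construction for relative ASA.
"""

from __future__ import annotations

import numpy as np

from .model import Atom, Residue, Structure

# ideal bond lengths (Å) and angles (degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |CD|, angle BCD and torsion ABCD."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(
    phi_psi: list[tuple[float, float]],
    sequence: str | None = None,
    chain_id: str = "A",
    start_num: int = 1,
    with_cb: bool = True,
    bfactor: float = 20.0,
) -> Structure:
    """Build a peptide with given per-residue (φ, ψ) in degrees.

    ``sequence`` is a one-letter string (default poly-alanine). φ of the
    first residue and ψ of the last are geometrically inert but accepted.
    """
    n_res = len(phi_psi)
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must match phi_psi length")

    from .io import _one_to_three

    coords_n: list[np.ndarray] = []
    coords_ca: list[np.ndarray] = []
    coords_c: list[np.ndarray] = []

    # first residue: N at origin, CA on x, C in the xy-plane
    coords_n.append(np.zeros(3))
    coords_ca.append(np.array([B_N_CA, 0.0, 0.0]))
    ang = np.deg2rad(180.0 - A_N_CA_C)
    coords_c.append(coords_ca[0] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]))

    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
                         B_C_N, A_CA_C_N, psi_prev)
        ca_i = place_atom(coords_ca[i - 1], coords_c[i - 1], n_i,
                          B_N_CA, A_C_N_CA, OMEGA)
        c_i = place_atom(coords_c[i - 1], n_i, ca_i,
                         B_CA_C, A_N_CA_C, phi_psi[i][0])
        coords_n.append(n_i)
        coords_ca.append(ca_i)
        coords_c.append(c_i)

    st = Structure(seqres={chain_id: sequence})
    residues: list[Residue] = []
    serial = 0
    for i in range(n_res):
        res_name = _one_to_three(sequence[i])
        res = Residue(chain_id=chain_id, seq_num=start_num + i, icode="",
                      res_name=res_name)
        psi = phi_psi[i][1] if i < n_res - 1 else 180.0
        o_i = place_atom(coords_n[i], coords_ca[i], coords_c[i],
                         B_C_O, A_CA_C_O, psi + 180.0)
        atom_defs = [("N", "N", coords_n[i]), ("CA", "C", coords_ca[i]),
                     ("C", "C", coords_c[i]), ("O", "O", o_i)]
        if with_cb and sequence[i] != "G":
            atom_defs.append(("CB", "C", _place_cb(coords_n[i], coords_ca[i], coords_c[i])))
        for name, elem, xyz in atom_defs:
            serial += 1
            res.atoms.append(Atom(serial=serial, name=name, element=elem,
                                  coords=xyz, bfactor=bfactor, occupancy=1.0,
                                  res_key=res.key))
        residues.append(res)
    st.chains[chain_id] = residues
    return st


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # tetrahedral Cβ from the bisector of N-Cα and C-Cα plus the plane normal
    u1 = (ca - n) / np.linalg.norm(ca - n)
    u2 = (ca - c) / np.linalg.norm(ca - c)
    bis = (u1 + u2) / np.linalg.norm(u1 + u2)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(54.75)  # half tetrahedral angle off the bisector plane
    direction = np.cos(half) * bis + np.sin(half) * perp
    return ca + B_CA_CB * direction


def extended_tripeptide(center_res: str) -> Structure:
    """Extended (φ=ψ=180°) ALA-X-ALA tripeptide with X full side chain.

    The central residue's side-chain atoms are grafted from biotite's ideal
    residue template, superposed onto the backbone N/Cα/C frame. Used to
    compute the per-residue-type reference ASA for relative accessibility.
    """
    seq = "A" + center_res.upper() + "A"
    st = build_chain([(180.0, 180.0)] * 3, sequence=seq, with_cb=True)
    if center_res.upper() in ("A", "G"):
        return st
    _graft_side_chain(st, chain_id="A", index=1)
    return st


def _graft_side_chain(st: Structure, chain_id: str, index: int) -> None:
    import biotite.structure.info as bstinfo

    from .superpose import superpose

    res = st.chains[chain_id][index]
    template = bstinfo.residue(res.res_name)
    heavy = template[template.element != "H"]

    def t_coord(name: str) -> np.ndarray:
        sel = heavy[heavy.atom_name == name]
        return np.asarray(sel.coord[0], dtype=float)

    frame_t = np.array([t_coord("N"), t_coord("CA"), t_coord("C")])
    frame_s = np.array([res.atom(n).coords for n in ("N", "CA", "C")])
    sup = superpose(frame_s, frame_t)

    backbone = {"N", "CA", "C", "O", "OXT"}
    # the template's own Cβ replaces the ideal-geometry one so that the
    # grafted side chain keeps its internal geometry exactly
    res.atoms = [a for a in res.atoms if a.name != "CB"]
    serial = max(a.serial for r in st.chains[chain_id] for a in r.atoms)
    for name, elem, xyz in zip(heavy.atom_name, heavy.element, heavy.coord):
        if name in backbone:
            continue
        serial += 1
        new = sup.rotation @ np.asarray(xyz, dtype=float) + sup.translation
        res.atoms.append(
            Atom(serial=serial, name=str(name), element=str(elem).upper(),
                 coords=new, bfactor=20.0, occupancy=1.0, res_key=res.key)
        )
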
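"""Accessible surface area by Shrake–Rupley sphere sampling.

Each heavy atom is given a solvent-expanded sphere of radius r_vdw + probe
(probe 1.4 Å, a water molecule). Test points quasi-uniformly covering the
sphere (Fibonacci lattice) are checked against every neighbor's expanded
sphere; the accessible fraction times the sphere area is the atom's ASA.

Relative (per-residue) ASA is the residue's absolute ASA as a percentage of
the same residue type's ASA in an extended ALA-X-ALA tripeptide, computed
once per residue type from ideal geometry. Residues under 25% relative ASA
count as buried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import ResKey, Structure

log = logging.getLogger(__name__)

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
BURIED_THRESHOLD = 25.0  # % relative ASA; strictly below counts buried


@lru_cache(maxsize=1)
def vdw_radii() -> dict[str, float]:
    """Element → van der Waals radius (Å), from the shipped Bondi table."""
    table: dict[str, float] = {}
    with resources.as_file(resources.files("confdiv.data") / "vdw_radii.txt") as p:
        for line in Path(p).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                el, r = line.split()
                table[el.upper()] = float(r)
    return table


DEFAULT_RADIUS = 1.80  # fallback for elements not in the table


def radius_of(element: str) -> float:
    table = vdw_radii()
    el = element.upper()
    if el not in table:
        log.warning("unknown element %r: default vdW radius %.2f Å", element,
                    DEFAULT_RADIUS)
    return table.get(el, DEFAULT_RADIUS)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class AsaRecord:
    per_atom: np.ndarray
    per_residue_abs: dict[ResKey, float]
    per_residue_rel: dict[ResKey, float | None]
    global_abs: float
    global_rel: float
    buried_fraction: float | None
    res_names: dict[ResKey, str] = field(default_factory=dict)


def atom_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom accessible surface area for a set of spheres."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    expanded = radii + probe_radius
    unit = fibonacci_sphere(n_sphere_points)
    out = np.zeros(n)
    if n == 0:
        return out
    tree = cKDTree(coords)
    max_exp = expanded.max()
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_exp)
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        pts = coords[i] + expanded[i] * unit
        if neighbors:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=2)
            free = ~(d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
        else:
            free = np.ones(n_sphere_points, dtype=bool)
        out[i] = free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


def asa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_N_POINTS,
    include_het: bool = False,
) -> AsaRecord:
    """ASA record for a structure's protein heavy atoms.

    Waters are always excluded; HET groups are excluded from both the
    surface and the occlusion set unless ``include_het`` is set (in which
    case they occlude but still carry no surface of their own).
    """
    protein_atoms = [
        a for r in structure.polymer_residues() for a in r.atoms
        if a.element.upper() != "H"
    ]
    occluders = list(protein_atoms)
    if include_het:
        occluders += [
            a for r in structure.het_residues() if not r.is_water
            for a in r.atoms if a.element.upper() != "H"
        ]
    coords = np.array([a.coords for a in occluders])
    radii = np.array([radius_of(a.element) for a in occluders])
    per_atom_all = atom_asa(coords, radii, probe_radius, n_sphere_points)
    per_atom = per_atom_all[: len(protein_atoms)]

    per_residue_abs: dict[ResKey, float] = {}
    res_names: dict[ResKey, str] = {}
    for a, area in zip(protein_atoms, per_atom):
        per_residue_abs[a.res_key] = per_residue_abs.get(a.res_key, 0.0) + float(area)
    for r in structure.polymer_residues():
        if r.key in per_residue_abs:
            res_names[r.key] = r.res_name

    per_residue_rel = {
        k: relative_asa(v, res_names[k], probe_radius, n_sphere_points)
        for k, v in per_residue_abs.items()
    }
    defined = [v for v in per_residue_rel.values() if v is not None]
    rec = AsaRecord(
        per_atom=per_atom,
        per_residue_abs=per_residue_abs,
        per_residue_rel=per_residue_rel,
        global_abs=float(sum(per_residue_abs.values())),
        global_rel=float(sum(defined)),
        buried_fraction=None,
        res_names=res_names,
    )
    rec.buried_fraction = buried_fraction(rec)
    return rec


@lru_cache(maxsize=8)
def reference_asa_table(
    probe_radius: float = DEFAULT_PROBE, n_sphere_points: int = DEFAULT_N_POINTS
) -> dict[str, float]:
    """Reference ASA of residue X in extended ALA-X-ALA, per residue type."""
    from .io import _ONE_TO_THREE
    from .peptide import extended_tripeptide

    table: dict[str, float] = {}
    for one, three in _ONE_TO_THREE.items():
        if three == "UNK":
            continue
        tri = extended_tripeptide(one)
        atoms = [a for r in tri.polymer_residues() for a in r.atoms]
        coords = np.array([a.coords for a in atoms])
        radii = np.array([radius_of(a.element) for a in atoms])
        areas = atom_asa(coords, radii, probe_radius, n_sphere_points)
        center_key = tri.chains["A"][1].key
        table[three] = float(
            sum(area for a, area in zip(atoms, areas) if a.res_key == center_key)
        )
    return table


def relative_asa(
    per_residue_abs: float,
    res_name: str,
    probe_radius: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> float | None:
    """Residue ASA as % of its extended ALA-X-ALA reference; may exceed 100."""
    table = reference_asa_table(probe_radius, n_sphere_points)
    ref = table.get(res_name)
    if ref is None or ref <= 0:
        log.warning("no reference ASA for residue type %r", res_name)
        return None
    return 100.0 * per_residue_abs / ref


def buried_fraction(asa_rec: AsaRecord) -> float | None:
    """% of residues with relative ASA strictly below 25 (25.0 is exposed)."""
    defined = [v for v in asa_rec.per_residue_rel.values() if v is not None]
    if not defined:
        return None
    buried = sum(1 for v in defined if v < BURIED_THRESHOLD)
    return 100.0 * buried / len(defined)
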
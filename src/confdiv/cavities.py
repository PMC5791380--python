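"""Interior cavity detection on a 3-D grid.

The protein is rasterized: grid points inside any solvent-expanded atom
sphere (r_vdw + probe) are occupied. Free space is segmented into
6-connected components; components reachable from the box boundary are
exterior solvent, and what remains are fully enclosed cavities. Volumes are
point counts times the cell volume; small components below a volume floor
are discarded as grid noise. Cavity flexibility is the mean min–max
normalized B-factor of the cavity's lining atoms.

Absolute volumes are method-dependent (alpha-sphere or Voronoi detectors
partition space differently), so comparisons across conformers — counts,
orderings, differences — are the intended use, not absolute agreement with
other programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .model import Structure
from .sasa import radius_of

log = logging.getLogger(__name__)

DEFAULT_GRID_SPACING = 0.8
DEFAULT_PROBE = 1.4
DEFAULT_MIN_VOLUME = 30.0
MAX_GRID_POINTS = 40_000_000


@dataclass
class Cavity:
    n_points: int
    volume: float
    lining_atoms: list[int]         # indices into the protein atom list
    flexibility: float | None = None


@dataclass
class CavitySet:
    cavities: list[Cavity] = field(default_factory=list)
    grid_spacing: float = DEFAULT_GRID_SPACING
    flexibility: float | None = None   # pooled over cavities

    @property
    def n_cavities(self) -> int:
        return len(self.cavities)

    @property
    def total_volume(self) -> float:
        return float(sum(c.volume for c in self.cavities))

    @property
    def max_volume(self) -> float:
        return float(max((c.volume for c in self.cavities), default=0.0))


def _protein_atoms(structure: Structure):
    return [a for r in structure.polymer_residues() for a in r.atoms
            if a.element.upper() != "H"]


def detect_cavities(
    structure: Structure,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    probe: float = DEFAULT_PROBE,
    min_volume: float = DEFAULT_MIN_VOLUME,
) -> CavitySet:
    """Fully enclosed interior voids of a structure.

    Surface pockets (concavities open to bulk solvent) are not counted:
    only components of free space with no 6-connected path to the grid
    boundary survive the exterior flood fill.
    """
    atoms = _protein_atoms(structure)
    if not atoms:
        raise ValueError("no protein atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([radius_of(a.element) for a in atoms]) + probe

    margin = 2.0 * (probe + radii.max())
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    spacing = grid_spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    while np.prod(shape) > MAX_GRID_POINTS:
        spacing *= 1.5
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
        log.warning("grid budget exceeded; coarsened spacing to %.2f Å", spacing)

    occupied = np.zeros(shape, dtype=bool)
    # rasterize each expanded sphere over its local sub-box
    for center, r in zip(coords, radii):
        lo_idx = np.floor((center - r - lo) / spacing).astype(int)
        hi_idx = np.ceil((center + r - lo) / spacing).astype(int) + 1
        lo_idx = np.maximum(lo_idx, 0)
        hi_idx = np.minimum(hi_idx, shape)
        ax = [np.arange(lo_idx[d], hi_idx[d]) * spacing + lo[d] for d in range(3)]
        dx = ax[0][:, None, None] - center[0]
        dy = ax[1][None, :, None] - center[1]
        dz = ax[2][None, None, :] - center[2]
        inside = dx * dx + dy * dy + dz * dz <= r * r
        occupied[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] |= inside

    free = ~occupied
    labels, n_labels = ndimage.label(free)  # 6-connectivity by default
    if n_labels == 0:
        return CavitySet(grid_spacing=spacing)
    boundary_labels = set()
    for axis in range(3):
        for face in (0, -1):
            sl: list = [slice(None)] * 3
            sl[axis] = face
            boundary_labels.update(np.unique(labels[tuple(sl)]))
    boundary_labels.discard(0)

    cell_volume = spacing ** 3
    tree = cKDTree(coords)
    cavities: list[Cavity] = []
    for lab in range(1, n_labels + 1):
        if lab in boundary_labels:
            continue
        pts_idx = np.argwhere(labels == lab)
        volume = len(pts_idx) * cell_volume
        if volume < min_volume:
            continue
        pts = pts_idx * spacing + lo
        lining = set()
        reach = radii.max() + spacing
        for hit in tree.query_ball_point(pts, reach):
            lining.update(hit)
        lining = sorted(
            i for i in lining
            if np.min(np.linalg.norm(coords[i] - pts, axis=1)) <= radii[i] + spacing
        )
        cavities.append(Cavity(n_points=len(pts_idx), volume=volume,
                               lining_atoms=lining))
    cavities.sort(key=lambda c: -c.volume)
    return CavitySet(cavities=cavities, grid_spacing=spacing)


def cavity_flexibility(cavity_set: CavitySet, structure: Structure) -> float | None:
    """Mean min–max normalized B-factor of cavity lining atoms.

    Normalization is over all protein atoms of the conformer:
    (B − Bmin) / (Bmax − Bmin); the conformer-level value is the mean over
    its cavities. Returns None when there are no cavities.
    """
    atoms = _protein_atoms(structure)
    b = np.array([a.bfactor for a in atoms])
    if len(b) == 0 or not cavity_set.cavities:
        cavity_set.flexibility = None
        return None
    bmin, bmax = b.min(), b.max()
    if bmax == bmin:
        log.warning("constant B-factors; cavity flexibility set to 0")
        norm = np.zeros_like(b)
    else:
        norm = (b - bmin) / (bmax - bmin)
    values = []
    for cav in cavity_set.cavities:
        if cav.lining_atoms:
            cav.flexibility = float(norm[cav.lining_atoms].mean())
            values.append(cav.flexibility)
    pooled = float(np.mean(values)) if values else None
    cavity_set.flexibility = pooled
    return pooled
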
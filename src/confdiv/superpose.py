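"""Least-squares rigid-body superposition (Kabsch) and pairwise Cα RMSD.

Conformers of one protein share a sequence, so pairing is by residue
identifier and no structural-alignment step is needed: the optimal proper
rotation comes from the SVD of the coordinate cross-covariance, with the
reflection corrected by the sign of its determinant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import ResKey, Structure

log = logging.getLogger(__name__)


class InsufficientPointsError(ValueError):
    pass


@dataclass
class Superposition:
    rotation: np.ndarray        # 3x3 proper rotation applied to coords_b
    translation: np.ndarray     # so that b' = b @ R.T + t approximates a
    rmsd: float
    per_site: np.ndarray        # per-point deviations |a_i - b'_i|, Å
    degenerate: bool = False    # collinear/planar-degenerate input flag


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal rigid superposition of ``coords_b`` onto ``coords_a``.

    Points are paired by index. Returns the proper rotation R and
    translation t minimizing RMS of ``a_i - (R b_i + t)``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"paired Nx3 arrays required, got {a.shape} / {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 paired points, got {n}")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T

    degenerate = s[1] < 1e-9 * max(s[0], 1.0)  # rank < 2: collinear points
    if degenerate:
        log.warning("degenerate (collinear) point set in superposition")

    b_fit = b0 @ rot.T + ca
    per_site = np.linalg.norm(a - b_fit, axis=1)
    rmsd = float(np.sqrt(np.mean(per_site**2)))
    translation = ca - rot @ cb
    return Superposition(rot, translation, rmsd, per_site, degenerate)


@dataclass
class PairRmsd:
    """Cα RMSD between two conformers over their common resolved residues."""

    rmsd: float
    per_site: np.ndarray
    residue_keys: list[ResKey] = field(default_factory=list)
    superposition: Superposition | None = None

    def per_site_map(self) -> dict[ResKey, float]:
        return dict(zip(self.residue_keys, self.per_site.tolist()))


def pair_rmsd(
    conf_a: Structure, conf_b: Structure, chain: str | None = None
) -> PairRmsd:
    """Superpose two conformers on their common Cα set and report RMSD.

    Residues missing (or lacking a Cα) in either conformer are excluded;
    the remaining Cα atoms are paired by (chain, residue number, icode).
    """
    map_a = conf_a.ca_map(chain)
    map_b = conf_b.ca_map(chain)
    common = sorted(set(map_a) & set(map_b))
    if len(common) < 3:
        raise InsufficientPointsError(
            f"only {len(common)} common resolved Cα between "
            f"{conf_a.id!r} and {conf_b.id!r}"
        )
    a = np.array([map_a[k] for k in common])
    b = np.array([map_b[k] for k in common])
    sup = superpose(a, b)
    return PairRmsd(sup.rmsd, sup.per_site, common, sup)
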
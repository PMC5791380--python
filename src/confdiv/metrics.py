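"""Per-conformer metric panel and pairwise deltas.

Collects the structural descriptors compared across crystallization
environments: global/relative ASA and buried fraction, radius of gyration,
hydrogen-bond count, three-state secondary structure, disordered regions
from missing electron density, and (optionally) interior cavities; plus
absolute differences of these between the two conformers of a pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import detect_missing
from .model import ResKey, Structure
from .sasa import AsaRecord, asa
from .secondary import SsString, assign_ss
from .superpose import PairRmsd

log = logging.getLogger(__name__)

ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
               "S": 32.06, "P": 30.974, "SE": 78.971}

IDR_MIN_LENGTH = 5
IDR_TERMINAL_EXCLUSION = 20


def radius_of_gyration(structure: Structure) -> float:
    """Mass-weighted radius of gyration over protein heavy atoms, Å."""
    atoms = [a for r in structure.polymer_residues() for a in r.atoms
             if a.element.upper() != "H"]
    if not atoms:
        raise ValueError("no protein atoms")
    coords = np.array([a.coords for a in atoms])
    masses = np.array([ATOMIC_MASS.get(a.element.upper(), 12.011) for a in atoms])
    center = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    sq = ((coords - center) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


@dataclass
class IdrSet:
    """Disordered regions: runs of ≥5 missing residues away from termini."""

    regions: list[tuple[str, int, int, int]]  # (chain, start, end, length)
    n_regions: int
    n_missing_residues: int


def find_idrs(structure: Structure) -> IdrSet:
    """Missing-density runs qualifying as intrinsically disordered regions.

    A run qualifies when, after clipping away the first and last 20
    positions of the chain (positions relative to SEQRES indexing), at
    least 5 consecutive missing residues remain. ``n_missing_residues``
    counts every missing residue regardless of the region rule.
    """
    runs = detect_missing(structure)
    n_missing = sum(end - start + 1 for _, start, end in runs)
    regions = []
    for chain_id, start, end in runs:
        offset = _chain_numbering_offset(structure, chain_id)
        length = _chain_length(structure, chain_id, offset)
        lo = offset + IDR_TERMINAL_EXCLUSION          # first allowed seq_num
        hi = offset + length - 1 - IDR_TERMINAL_EXCLUSION  # last allowed
        cs, ce = max(start, lo), min(end, hi)
        if ce - cs + 1 >= IDR_MIN_LENGTH:
            regions.append((chain_id, cs, ce, ce - cs + 1))
    return IdrSet(regions=regions, n_regions=len(regions),
                  n_missing_residues=n_missing)


def _chain_numbering_offset(structure: Structure, chain_id: str) -> int:
    nums = [r.seq_num for r in structure.chains.get(chain_id, []) if not r.is_het]
    nums += [s for c, s, _ in structure.missing_residues if c == chain_id]
    return min(nums) if nums else 1


def _chain_length(structure: Structure, chain_id: str, offset: int) -> int:
    if chain_id in structure.seqres:
        return len(structure.seqres[chain_id])
    nums = [r.seq_num for r in structure.chains.get(chain_id, []) if not r.is_het]
    nums += [s for c, s, _ in structure.missing_residues if c == chain_id]
    return (max(nums) - offset + 1) if nums else 0


@dataclass
class MetricPanel:
    """All per-conformer metric values used in the subgroup comparisons."""

    structure_id: str
    asa: AsaRecord
    rg: float
    n_hbonds: int
    ss: SsString
    idrs: IdrSet
    seq_length: int
    cavities: "object | None" = None  # CavitySet, filled by the cavity stage

    def row(self) -> dict:
        out = {
            "id": self.structure_id,
            "global_asa": self.asa.global_abs,
            "relative_asa": self.asa.global_rel,
            "buried_pct": self.asa.buried_fraction,
            "rg": self.rg,
            "n_hbonds": self.n_hbonds,
            "n_idr_regions": self.idrs.n_regions,
            "n_missing_residues": self.idrs.n_missing_residues,
        }
        if self.cavities is not None:
            out.update({
                "n_cavities": self.cavities.n_cavities,
                "total_cavity_volume": self.cavities.total_volume,
                "max_cavity_volume": self.cavities.max_volume,
                "cavity_flexibility": self.cavities.flexibility,
            })
        return out


def compute_panel(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    with_cavities: bool = False,
    cavity_kwargs: dict | None = None,
) -> MetricPanel:
    chain = next(iter(structure.chains))
    seq_len = _chain_length(structure, chain,
                            _chain_numbering_offset(structure, chain))
    from .hbonds import count_hbonds

    panel = MetricPanel(
        structure_id=structure.id,
        asa=asa(structure, probe_radius, n_sphere_points),
        rg=radius_of_gyration(structure),
        n_hbonds=count_hbonds(structure),
        ss=assign_ss(structure),
        idrs=find_idrs(structure),
        seq_length=max(seq_len, 1),
    )
    if with_cavities:
        from .cavities import cavity_flexibility, detect_cavities

        cs = detect_cavities(structure, **(cavity_kwargs or {}))
        cavity_flexibility(cs, structure)
        panel.cavities = cs
    return panel


def active_site_metrics(
    pair: PairRmsd,
    asa_a: AsaRecord,
    asa_b: AsaRecord,
    site_residues: list[tuple[str, int]],
) -> dict[str, float | None]:
    """Mean per-site deviation and relative-ASA shift at catalytic residues.

    Uses the already-computed global superposition (no re-fit on the site)
    and reports the ASA shift as a fraction (relative ASA difference / 100).
    """
    site = {(c, s) for c, s in site_residues}
    per_site = pair.per_site_map()
    devs = [d for (c, s, _i), d in per_site.items() if (c, s) in site]

    rel_diffs = []
    rel_b = {k: v for k, v in asa_b.per_residue_rel.items()}
    for key, va in asa_a.per_residue_rel.items():
        c, s, _ = key
        if (c, s) not in site:
            continue
        vb = rel_b.get(key)
        if va is not None and vb is not None:
            rel_diffs.append(abs(va - vb) / 100.0)

    if not devs:
        log.info("no active-site residue resolved in both conformers")
        return {"site_rmsd": None, "site_rel_asa_diff": None}
    return {
        "site_rmsd": float(np.mean(devs)),
        "site_rel_asa_diff": float(np.mean(rel_diffs)) if rel_diffs else None,
    }


@dataclass
class PairDeltas:
    d_global_asa: float
    d_relative_asa: float
    d_n_idr_regions: int
    d_missing_fraction: float
    d_n_missing: int
    d_hbonds: int
    d_rg: float
    extras: dict = field(default_factory=dict)

    def row(self) -> dict:
        return {
            "d_global_asa": self.d_global_asa,
            "d_relative_asa": self.d_relative_asa,
            "d_n_idr_regions": self.d_n_idr_regions,
            "d_n_missing": self.d_n_missing,
            "d_missing_fraction": self.d_missing_fraction,
            "d_hbonds": self.d_hbonds,
            "d_rg": self.d_rg,
            **self.extras,
        }


def pair_deltas(panel_a: MetricPanel, panel_b: MetricPanel) -> PairDeltas:
    """Absolute metric differences between the two conformers of a pair."""
    frac_a = panel_a.idrs.n_missing_residues / panel_a.seq_length
    frac_b = panel_b.idrs.n_missing_residues / panel_b.seq_length
    deltas = PairDeltas(
        d_global_asa=abs(panel_a.asa.global_abs - panel_b.asa.global_abs),
        d_relative_asa=abs(panel_a.asa.global_rel - panel_b.asa.global_rel),
        d_n_idr_regions=abs(panel_a.idrs.n_regions - panel_b.idrs.n_regions),
        d_missing_fraction=abs(frac_a - frac_b),
        d_n_missing=abs(panel_a.idrs.n_missing_residues
                        - panel_b.idrs.n_missing_residues),
        d_hbonds=abs(panel_a.n_hbonds - panel_b.n_hbonds),
        d_rg=abs(panel_a.rg - panel_b.rg),
    )
    if panel_a.cavities is not None and panel_b.cavities is not None:
        deltas.extras["d_total_cavity_volume"] = abs(
            panel_a.cavities.total_volume - panel_b.cavities.total_volume
        )
        deltas.extras["d_n_cavities"] = abs(
            panel_a.cavities.n_cavities - panel_b.cavities.n_cavities
        )
    return deltas
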
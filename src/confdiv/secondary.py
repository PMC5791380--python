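"""Three-state secondary structure from backbone hydrogen-bond patterns.

Backbone N-H···O=C bonds are scored with the Kabsch–Sander electrostatic
energy

    E = 0.084 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN) * 332  kcal/mol

(with the amide H placed 1 Å from N, anti to the preceding carbonyl) and a
bond is assigned when E < -0.5 kcal/mol. Helices (α, 3₁₀, π — all reported
as H) arise from consecutive i→i+3/4/5 turns, strands and bridges (E) from
parallel/antiparallel bridge patterns, and everything else is loop (L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import ResKey, Structure

log = logging.getLogger(__name__)

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_Q = 0.084 * 332.0


@dataclass
class SsString:
    codes: str                  # one of H/E/L per resolved residue
    residue_keys: list[ResKey]

    def as_map(self) -> dict[ResKey, str]:
        return dict(zip(self.residue_keys, self.codes))

    def __len__(self) -> int:
        return len(self.codes)


def _backbone_frames(structure: Structure, chain: str):
    """Per-residue backbone coordinates (N, CA, C, O) and amide H."""
    residues = [r for r in structure.polymer_residues(chain)]
    frames = []
    for i, r in enumerate(residues):
        atoms = {n: r.atom(n) for n in ("N", "CA", "C", "O")}
        if any(v is None for v in atoms.values()):
            frames.append(None)
            continue
        entry = {n: a.coords for n, a in atoms.items()}
        entry["res"] = r
        # chain break check for H placement and turn patterns
        prev = residues[i - 1] if i > 0 else None
        contiguous = (
            prev is not None
            and prev.seq_num == r.seq_num - 1
            and prev.atom("C") is not None
            and prev.atom("O") is not None
        )
        if contiguous and r.res_name != "PRO":
            c_prev, o_prev = prev.atom("C").coords, prev.atom("O").coords
            d = c_prev - o_prev
            entry["H"] = entry["N"] + d / np.linalg.norm(d)
        else:
            entry["H"] = None  # N-terminal or proline: no donor H
        frames.append(entry)
    return residues, frames


def ks_energy(donor, acceptor) -> float:
    """Kabsch–Sander energy of N-H(donor residue) ··· O=C(acceptor residue)."""
    if donor is None or acceptor is None or donor["H"] is None:
        return 0.0
    n, h = donor["N"], donor["H"]
    c, o = acceptor["C"], acceptor["O"]
    d_on = np.linalg.norm(o - n)
    d_ch = np.linalg.norm(c - h)
    d_oh = np.linalg.norm(o - h)
    d_cn = np.linalg.norm(c - n)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:
        return -9.9  # atom clash; treat as bonded (DSSP convention)
    return _KS_Q * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)


def assign_ss(structure: Structure, chain: str | None = None) -> SsString:
    """Assign H/E/L per resolved residue.

    Residues with missing backbone atoms are coded L (and logged). Helix
    takes precedence over strand when patterns overlap.
    """
    chains = [chain] if chain is not None else list(structure.chains)
    residues: list = []
    frames: list = []
    chain_of: list[str] = []
    for ch in chains:
        res_c, frames_c = _backbone_frames(structure, ch)
        residues.extend(res_c)
        frames.extend(frames_c)
        chain_of.extend([ch] * len(res_c))
    if not residues:
        return SsString("", [])
    n = len(residues)
    for i, f in enumerate(frames):
        if f is None:
            log.info("%s %s: missing backbone atoms, coded L",
                     structure.id, residues[i].key)

    def contiguous(i: int, j: int) -> bool:
        """Residues i..j form an unbroken stretch of one chain."""
        if not (0 <= i < n and 0 <= j < n):
            return False
        return (
            chain_of[i] == chain_of[j]
            and residues[j].seq_num - residues[i].seq_num == j - i
        )

    # hbond(i, j): CO of residue i accepts the NH of residue j
    def hbond(i: int, j: int) -> bool:
        if not (0 <= i < n and 0 <= j < n):
            return False
        return ks_energy(frames[j], frames[i]) < HB_ENERGY_CUTOFF

    codes = ["L"] * n

    # n-turns → helix: two consecutive turns at i-1 and i mark i..i+k-1;
    # turns only apply within an unbroken stretch of one chain
    for k in (4, 3, 5):  # α first, then 3₁₀ and π (all map to H)
        turn = [hbond(i, i + k) and contiguous(i, i + k) for i in range(n)]
        for i in range(1, n):
            if turn[i - 1] and turn[i]:
                for j in range(i, min(i + k, n)):
                    codes[j] = "H"

    # bridges → strand (intra- or inter-chain)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if chain_of[i] == chain_of[j] and abs(
                    residues[j].seq_num - residues[i].seq_num) <= 2:
                continue
            parallel = (hbond(j, i - 1) and hbond(i + 1, j)) or (
                hbond(i, j - 1) and hbond(j + 1, i)
            )
            antiparallel = (hbond(j, i) and hbond(i, j)) or (
                hbond(j + 1, i - 1) and hbond(i + 1, j - 1)
            )
            if parallel or antiparallel:
                if codes[i] == "L":
                    codes[i] = "E"
                if codes[j] == "L":
                    codes[j] = "E"

    # residues without a full backbone stay L even inside spanned patterns
    for i, f in enumerate(frames):
        if f is None:
            codes[i] = "L"
    return SsString("".join(codes), [r.key for r in residues])


def ss_element_rmsd(
    per_site: dict[ResKey, float] | None,
    ss: SsString,
    per_site_vector: np.ndarray | None = None,
) -> dict[str, float]:
    """Mean per-site deviation within each secondary-structure class.

    ``per_site`` maps residue keys to Cα deviations (from a pair
    superposition); classes come from one conformer's assignment. Classes
    with no residues are absent from the result.
    """
    if per_site is None:
        raise ValueError("per-site deviations required")
    ss_map = ss.as_map()
    sums: dict[str, list[float]] = {}
    for key, dev in per_site.items():
        cls = ss_map.get(key)
        if cls is None:
            continue
        sums.setdefault(cls, []).append(dev)
    return {cls: float(np.mean(v)) for cls, v in sums.items()}
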
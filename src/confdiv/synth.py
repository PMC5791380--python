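"""Seeded synthetic conformer ensembles with prescribed statistical structure.

Backbones are built from ideal dihedrals per secondary-structure segment;
conformers are displaced along smooth low-frequency chain modes (not i.i.d.
atomic noise) so per-site deviation profiles resemble real conformational
change, and displacement amplitudes are calibrated so that the maximum-RMSD
pair of each AA/AO/OO subgroup hits its prescribed Cα RMSD. Organic-solvent
HETATM groups, cognate ligands, missing-residue regions and B-factor fields
are injected on top, with a truth record of every generated parameter.

Default pairwise targets (AA 0.97 Å, AO 0.94 Å, OO 0.68 Å, spread 0.15 Å)
are the study conditions the comparisons are designed around: aqueous pairs
spread about twice as wide as non-aqueous ones.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .io import write_pdb
from .model import Atom, Residue, Structure
from .peptide import build_chain
from .superpose import pair_rmsd

IDEAL_PHI_PSI = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}
COIL_PHI_RANGE = (-160.0, -60.0)
COIL_PSI_RANGE = (90.0, 180.0)

DEFAULT_TARGETS = {"AA": 0.97, "AO": 0.94, "OO": 0.68}
DEFAULT_SPREAD = 0.15


@dataclass
class EnsembleSpec:
    """Generator parameters for one protein's conformer ensemble."""

    n_residues: int = 64
    ss_layout: str | None = None          # e.g. "H18L8E10L8H12L8" or per-residue
    n_aqueous: int = 2
    n_organic: int = 2
    target_rmsd: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_TARGETS))
    rmsd_spread: float = DEFAULT_SPREAD   # per-protein s.d. used by benchmarks
    solvent_codes: list[str] = dc_field(default_factory=lambda: ["EOH", "DMF"])
    ligand_code: str | None = None
    missing_regions: list[tuple[int, int, list[int] | None]] = dc_field(
        default_factory=list)              # (start_seq, length, conformer idxs)
    b_baseline: float = 20.0
    b_noise_sd: float = 2.0
    b_loop_multiplier: float = 1.5
    resolution: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 30:
            raise ValueError("n_residues must be >= 30")
        if any(v < 0 for v in self.target_rmsd.values()):
            raise ValueError("target RMSDs must be >= 0")

    def layout(self) -> str:
        if self.ss_layout is None:
            base = "H18L8E10L8H12L8"
            expanded = expand_layout(base)
            reps = -(-self.n_residues // len(expanded))
            return (expanded * reps)[: self.n_residues]
        expanded = expand_layout(self.ss_layout)
        if len(expanded) != self.n_residues:
            raise ValueError(
                f"ss_layout covers {len(expanded)} residues, spec says "
                f"{self.n_residues}"
            )
        return expanded


def expand_layout(layout: str) -> str:
    """Expand segment notation 'H12L6' to a per-residue string; validates."""
    if not layout:
        raise ValueError("empty ss_layout")
    if re.fullmatch(r"[HEL]+", layout):
        return layout
    out = []
    for code, count in re.findall(r"([HEL])(\d+)", layout):
        out.append(code * int(count))
    expanded = "".join(out)
    if not expanded or not re.fullmatch(r"([HEL]\d+)+", layout):
        raise ValueError(f"invalid ss_layout {layout!r}")
    return expanded


def build_backbone(spec: EnsembleSpec) -> Structure:
    """Ideal-geometry poly-ALA backbone following the spec's SS layout."""
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout()
    phi_psi = []
    for code in layout:
        if code in IDEAL_PHI_PSI:
            phi_psi.append(IDEAL_PHI_PSI[code])
        else:
            phi_psi.append((rng.uniform(*COIL_PHI_RANGE),
                            rng.uniform(*COIL_PSI_RANGE)))
    st = build_chain(phi_psi, sequence="A" * spec.n_residues)
    st.resolution = spec.resolution
    # B-factor field: baseline + noise, loops elevated
    for i, r in enumerate(st.chains["A"]):
        b = spec.b_baseline + rng.normal(0.0, spec.b_noise_sd)
        if layout[i] == "L":
            b *= spec.b_loop_multiplier
        b = max(b, 2.0)
        for a in r.atoms:
            a.bfactor = b
    return st


# ---------------------------------------------------------------- mode fields

def _smooth_field(n: int, rng: np.random.Generator, n_modes: int = 5) -> np.ndarray:
    """Per-residue 3-vector field from low-frequency sinusoidal chain modes."""
    i = np.arange(n) + 0.5
    out = np.zeros((n, 3))
    for axis in range(3):
        for m in range(1, n_modes + 1):
            amp = rng.normal(0.0, 1.0) / m
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out[:, axis] += amp * np.sin(np.pi * m * i / n + phase)
    return out


def _rigid_basis(ca: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes in R^{3N}."""
    n = len(ca)
    centered = ca - ca.mean(axis=0)
    modes = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        modes.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        modes.append(np.cross(e, centered).ravel())
    b = np.array(modes).T
    q, _ = np.linalg.qr(b)
    return q


def _orthogonal_modes(ca: np.ndarray, rng: np.random.Generator,
                      k: int = 3) -> list[np.ndarray]:
    """k smooth fields, orthogonal to rigid modes and each other, RMS 1 Å."""
    n = len(ca)
    q = _rigid_basis(ca)
    modes: list[np.ndarray] = []
    while len(modes) < k:
        f = _smooth_field(n, rng).ravel()
        f -= q @ (q.T @ f)
        for m in modes:
            f -= m * (m @ f) / (m @ m)
        norm = np.linalg.norm(f)
        if norm < 1e-6:
            continue
        f *= np.sqrt(n) / norm  # RMS displacement per residue = 1 Å
        modes.append(f)
    return [m.reshape(n, 3) for m in modes]


def _displace(structure: Structure, field: np.ndarray) -> Structure:
    """New structure with residue i's atoms shifted by field[i] (polymer only)."""
    out = structure.copy()
    chain = next(iter(out.chains))
    poly = [r for r in out.chains[chain] if not r.is_het]
    if len(poly) != len(field):
        raise ValueError("field length must equal residue count")
    for r, d in zip(poly, field):
        for a in r.atoms:
            a.coords = a.coords + d
    return out


def perturb_to_rmsd(
    structure: Structure,
    target: float,
    mode: str = "global-breathing",
    seed: int | None = None,
    site_residues: list[tuple[str, int]] | None = None,
    tol: float = 0.02,
) -> Structure:
    """A conformer at a prescribed Cα RMSD from the input (within 5%).

    ``mode`` restricts the displacement: 'global-breathing' moves the whole
    chain, 'loop-only' only L residues (by the structure's own secondary
    structure), 'site-only' only the named residues. The smooth random field
    is rescaled iteratively against the measured post-superposition RMSD.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    if target == 0:
        return structure.copy()
    rng = np.random.default_rng(seed)
    chain = next(iter(structure.chains))
    poly = [r for r in structure.chains[chain] if not r.is_het]
    n = len(poly)
    field = _smooth_field(n, rng)

    if mode == "loop-only":
        from .secondary import assign_ss

        ss = assign_ss(structure, chain)
        ss_map = ss.as_map()
        mask = np.array([ss_map.get(r.key, "L") == "L" for r in poly])
    elif mode == "site-only":
        if not site_residues:
            raise ValueError("site-only mode needs site_residues")
        site = {(c, s) for c, s in site_residues}
        mask = np.array([(r.chain_id, r.seq_num) in site for r in poly])
    elif mode == "global-breathing":
        mask = np.ones(n, dtype=bool)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    field[~mask] = 0.0
    rms = np.sqrt((field**2).sum(axis=1).mean())
    if rms < 1e-12:
        raise ValueError("empty displacement mask")
    field *= target / rms

    from .superpose import superpose

    ca = np.array([r.atom("CA").coords for r in poly])
    for _ in range(25):
        achieved = superpose(ca, ca + field).rmsd
        if abs(achieved - target) <= tol * target:
            break
        field *= target / max(achieved, 1e-9)
    return _displace(structure, field)


def build_antiparallel_sheet(n_residues: int = 8) -> Structure:
    """Two ideal antiparallel β-strands (chains A and B) in register.

    Strand dihedrals φ=−139°, ψ=135°; the second strand is the first rotated
    180° about the inter-strand offset axis and shifted 3.8 Å, a geometry
    whose inter-chain backbone contacts score as Kabsch–Sander hydrogen
    bonds. Used to exercise bridge/strand assignment.
    """
    s1 = build_chain([(-139.0, 135.0)] * n_residues, with_cb=False)
    ca = np.array([r.atom("CA").coords for r in s1.chains["A"]])
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    center = ca.mean(axis=0)
    perp = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], axis) * axis
    perp /= np.linalg.norm(perp)
    yoff, xoff = 3.8, -1.6  # offsets registering the H-bond ladder
    st = s1.copy()
    s2 = s1.copy()
    for r in s2.chains["A"]:
        r.chain_id = "B"
        for a in r.atoms:
            v = a.coords - center
            flipped = center + np.dot(v, perp) * perp - (v - np.dot(v, perp) * perp)
            a.coords = flipped + perp * yoff + axis * xoff
            a.res_key = (r.chain_id, r.seq_num, r.icode)
    st.chains["B"] = s2.chains["A"]
    st.seqres["B"] = st.seqres["A"]
    return st


# ------------------------------------------------------------- HET injection

def inject_het(
    structure: Structure,
    code: str,
    n_copies: int = 1,
    placement: str = "surface",
    element: str = "C",
) -> Structure:
    """Add single-atom HETATM groups with the given residue code."""
    code = code.upper()
    if not (1 <= len(code) <= 3) or not code.isalnum():
        raise ValueError(f"invalid HET code {code!r}")
    out = structure.copy()
    if n_copies == 0:
        return out
    chain = next(iter(out.chains))
    atoms = np.array([a.coords for r in out.polymer_residues() for a in r.atoms])
    centroid = atoms.mean(axis=0)
    rmax = np.max(np.linalg.norm(atoms - centroid, axis=1))
    serial = max((a.serial for r in out.chains[chain] for a in r.atoms), default=0)
    seq0 = max((r.seq_num for r in out.chains[chain]), default=0) + 100
    for i in range(n_copies):
        if placement == "surface":
            direction = np.array([np.cos(2.4 * i), np.sin(2.4 * i),
                                  0.3 * ((i % 3) - 1)])
            direction /= np.linalg.norm(direction)
            pos = centroid + direction * (rmax + 5.0 + 3.0 * i)
        elif placement == "cavity":
            pos = centroid
        else:
            raise ValueError(f"unknown placement {placement!r}")
        if atoms.size and np.min(np.linalg.norm(atoms - pos, axis=1)) < 2.0:
            raise ValueError("no non-clashing placement found")
        serial += 1
        res = Residue(chain_id=chain, seq_num=seq0 + i, icode="",
                      res_name=code, is_het=True)
        res.atoms.append(Atom(serial=serial, name=element, element=element,
                              coords=pos, bfactor=30.0, occupancy=1.0,
                              is_het=True, res_key=res.key))
        out.chains[chain].append(res)
    return out


def inject_missing(structure: Structure, start: int, length: int) -> Structure:
    """Remove coordinates for a residue range and record it as missing."""
    out = structure.copy()
    chain = next(iter(out.chains))
    poly_nums = {r.seq_num for r in out.chains[chain] if not r.is_het}
    region = set(range(start, start + length))
    if not region <= poly_nums:
        raise ValueError(
            f"region {start}..{start + length - 1} not fully within chain")
    removed = [r for r in out.chains[chain]
               if not r.is_het and r.seq_num in region]
    out.chains[chain] = [r for r in out.chains[chain]
                         if r.is_het or r.seq_num not in region]
    for r in removed:
        out.missing_residues.append((chain, r.seq_num, r.res_name))
    out.missing_residues.sort(key=lambda t: (t[0], t[1]))
    out.has_remark465 = True
    return out


# -------------------------------------------------------------- full studies

def make_study(spec: EnsembleSpec, protein_id: str = "p000"):
    """One protein's conformer ensemble plus its truth record.

    Aqueous conformers a1, a2, ... and organic-medium conformers o1, o2, ...
    are placed in orthogonal smooth-mode space so that the maximum pair of
    each subgroup matches the prescribed target: |a1−a2| = t_AA along mode 1,
    the o-cluster sits on mode 1 at the offset making the widest AO pair
    equal t_AO, and |o1−o2| = t_OO along mode 3. Amplitudes are calibrated
    against measured post-superposition RMSDs.
    """
    if spec.n_aqueous + spec.n_organic < 2:
        raise ValueError("need at least 2 conformers")
    if "OO" in spec.target_rmsd and spec.n_organic < 2:
        raise ValueError("OO subgroup requested with fewer than 2 O conformers")
    if "AA" in spec.target_rmsd and spec.n_aqueous < 2:
        raise ValueError("AA subgroup requested with fewer than 2 A conformers")
    rng = np.random.default_rng(spec.seed)
    base = build_backbone(spec)
    chain = next(iter(base.chains))
    ca = np.array([r.atom("CA").coords for r in base.chains[chain]])
    f1, f2, f3 = _orthogonal_modes(ca, rng, k=3)

    t_aa = spec.target_rmsd.get("AA", DEFAULT_TARGETS["AA"])
    t_ao = spec.target_rmsd.get("AO", DEFAULT_TARGETS["AO"])
    t_oo = spec.target_rmsd.get("OO", DEFAULT_TARGETS["OO"])
    t_ao = max(t_ao, t_oo + 0.02)  # geometric floor: widest AO pair >= OO span

    from .superpose import superpose

    def measure(amp_field, ref_field=None) -> float:
        # calibration runs on bare Cα arrays; pair_rmsd reduces to this
        a_c = ca if ref_field is None else ca + ref_field
        return superpose(a_c, ca + amp_field).rmsd

    # calibrate amplitudes against the nonlinearity of superposition
    a = t_aa if t_aa > 0 else 0.0
    for _ in range(4):
        if a == 0:
            break
        a *= t_aa / max(measure(a * f1), 1e-9)
    b = t_oo if t_oo > 0 else 0.0
    for _ in range(4):
        if b == 0:
            break
        b *= t_oo / max(measure(b * f3), 1e-9)
    s = np.sqrt(max(t_ao**2 - t_oo**2, 1e-6))
    m = max(s, a / 2.0)
    for _ in range(6):
        o2_field = m * f1 + b * f3
        widest = max(measure(o2_field), measure(m * f1),
                     measure(o2_field, ref_field=a * f1))
        m *= t_ao / max(widest, 1e-9)
        m = max(m, a / 2.0)

    conformers: list[Structure] = []
    labels: dict[str, str] = {}
    fields: list[np.ndarray] = []
    for i in range(spec.n_aqueous):
        if i == 0:
            f = np.zeros_like(f1)
        elif i == 1:
            f = a * f1
        else:  # extras jitter near a1 without overtaking the designed max
            f = 0.15 * t_aa * rng.normal() * f2
        fields.append(f)
        labels[f"{protein_id}a{i + 1}"] = "A"
    for i in range(spec.n_organic):
        if i == 0:
            f = m * f1
        elif i == 1:
            f = m * f1 + b * f3
        else:
            f = m * f1 + 0.15 * t_oo * rng.normal() * f2
        fields.append(f)
        labels[f"{protein_id}o{i + 1}"] = "O"

    ids = list(labels)
    for idx, (cid, f) in enumerate(zip(ids, fields)):
        st = _displace(base, f)
        st.id = cid
        st.resolution = spec.resolution
        if labels[cid] == "O":
            code = spec.solvent_codes[idx % len(spec.solvent_codes)]
            st = inject_het(st, code, n_copies=1, placement="surface")
            st.id = cid
        if spec.ligand_code:
            st = inject_het(st, spec.ligand_code, n_copies=1,
                            placement="surface", element="P")
            st.id = cid
        for start, length, which in spec.missing_regions:
            if which is None or idx in which:
                st = inject_missing(st, start, length)
                st.id = cid
        conformers.append(st)

    achieved = {}
    if spec.n_aqueous >= 2:
        achieved["AA"] = pair_rmsd(conformers[0], conformers[1], chain).rmsd
    if spec.n_organic >= 2:
        o0 = spec.n_aqueous
        achieved["OO"] = pair_rmsd(conformers[o0], conformers[o0 + 1], chain).rmsd
    if spec.n_aqueous >= 1 and spec.n_organic >= 1:
        achieved["AO"] = max(
            pair_rmsd(ca_, cb_, chain).rmsd
            for ca_ in conformers[: spec.n_aqueous]
            for cb_ in conformers[spec.n_aqueous:]
        )
    truth = {
        "protein_id": protein_id,
        "seed": int(spec.seed),
        "targets": {"AA": t_aa, "AO": t_ao, "OO": t_oo},
        "achieved": achieved,
        "labels": labels,
        "bound": {cid: bool(spec.ligand_code) for cid in ids},
    }
    return conformers, truth


def make_benchmark(
    n_proteins: int = 50,
    seed: int = 0,
    base_spec: EnsembleSpec | None = None,
    rmsd_means: dict[str, float] | None = None,
    rmsd_spread: float | None = None,
):
    """A multi-protein study: per-protein targets drawn around subgroup means."""
    template = base_spec or EnsembleSpec()
    means = rmsd_means or dict(template.target_rmsd)
    spread = template.rmsd_spread if rmsd_spread is None else rmsd_spread
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_proteins * 2).reshape(n_proteins, 2)
    all_structs: list[Structure] = []
    truths: list[dict] = []
    for p in range(n_proteins):
        rng = np.random.default_rng(child_seeds[p, 0])
        targets = {
            sg: float(max(rng.normal(means[sg], spread), 0.05))
            for sg in ("AA", "AO", "OO")
        }
        spec = EnsembleSpec(
            n_residues=template.n_residues,
            ss_layout=template.ss_layout,
            n_aqueous=template.n_aqueous,
            n_organic=template.n_organic,
            target_rmsd=targets,
            rmsd_spread=spread,
            solvent_codes=list(template.solvent_codes),
            ligand_code=template.ligand_code,
            missing_regions=list(template.missing_regions),
            b_baseline=template.b_baseline,
            b_noise_sd=template.b_noise_sd,
            b_loop_multiplier=template.b_loop_multiplier,
            resolution=template.resolution,
            seed=int(child_seeds[p, 1] % (2**31 - 1)),
        )
        confs, truth = make_study(spec, protein_id=f"p{p:03d}")
        all_structs.extend(confs)
        truths.append(truth)
    return all_structs, truths


def write_study(
    out_dir: str | Path, structures: list[Structure], truths: list[dict]
) -> Path:
    """Write a study as a PDB directory, a manifest TSV and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["protein_id\tpdb_path\tchain\thas_mutations"]
    by_protein = {t["protein_id"]: t for t in truths}
    for st in structures:
        path = out / f"{st.id}.pdb"
        path.write_text(write_pdb(st))
        pid = next(p for p in by_protein if st.id.startswith(p))
        chain = next(iter(st.chains))
        rows.append(f"{pid}\t{path.name}\t{chain}\t0")
    (out / "manifest.tsv").write_text("\n".join(rows) + "\n")
    (out / "truth.json").write_text(json.dumps(truths, indent=2))
    return out
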
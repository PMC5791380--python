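"""PDB reading and writing.

Coordinate and header parsing is delegated to gemmi; this module maps the
first model into the pipeline's :class:`~confdiv.model.Structure`, applying
the single-conformation policy (highest-occupancy altloc, ties broken by
altloc letter), and supplements gemmi with a REMARK 465 scan, since missing
electron density is primary evidence for the disorder analysis.

Writing is done directly in fixed-column PDB v3.3 so that the round trip
``parse_pdb(write_pdb(s)) == s`` holds exactly on atoms, HET codes and
missing-residue records for every structure the synthetic generator emits.
"""

from __future__ import annotations

import logging
import re

import gemmi

from .model import Atom, Residue, Structure

log = logging.getLogger(__name__)


class PdbFormatError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


_REMARK465_RE = re.compile(
    r"^REMARK 465\s+(?:\d+\s+)?([A-Z0-9]{2,3})\s+(\S)\s+(-?\d+)[A-Za-z]?\s*$"
)

# residues whose one-letter code comes from a parent standard residue (MSE -> M, ...)
def three_to_one(res_name: str) -> str:
    info = gemmi.find_tabulated_residue(res_name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformation per atom name; ties prefer altloc 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        picked.append(group[0])
    return picked


def parse_pdb(text: str, chain_filter: str | None = None, id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Parameters
    ----------
    text
        PDB-format character stream.
    chain_filter
        If given, only this chain's residues (ATOM and HETATM) are kept.
    id
        Identifier to attach; defaults to the HEADER id when present.
    """
    if not text.strip():
        raise PdbFormatError("empty PDB text")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise PdbFormatError(str(exc)) from exc

    out = Structure(id=id or (st.name.lower() if st.name else ""))
    out.resolution = st.resolution if st.resolution > 0 else None

    if len(st) == 0:
        raise EmptyStructureError("no models in PDB input")
    model = st[0]  # X-ray inputs are single-model; NMR-style extras ignored

    for ch in model:
        if chain_filter is not None and ch.name != chain_filter:
            continue
        residues: list[Residue] = []
        for gres in ch:
            info = gemmi.find_tabulated_residue(gres.name)
            # modified residues (MSE, ...) on HETATM records are polymer
            is_het = gres.het_flag == "H" and not (
                info is not None and info.is_amino_acid()
            )
            res = Residue(
                chain_id=ch.name,
                seq_num=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                res_name=gres.name,
                is_het=is_het,
            )
            for ga in _pick_altlocs(gres):
                res.atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name or _infer_element(ga.name),
                        coords=[ga.pos.x, ga.pos.y, ga.pos.z],
                        bfactor=ga.b_iso,
                        occupancy=ga.occ,
                        is_het=is_het,
                        res_key=(ch.name, gres.seqid.num, (gres.seqid.icode or "").strip()),
                    )
                )
            residues.append(res)
        if residues:
            residues.sort(key=lambda r: (r.seq_num, r.icode))
            out.chains[ch.name] = residues

    if not out.chains:
        raise EmptyStructureError(
            f"no residues selected (chain_filter={chain_filter!r})"
        )

    # SEQRES via gemmi entities
    st.setup_entities()
    for ch in st[0]:
        if ch.name not in out.chains:
            continue
        ent = st.get_entity_of(ch.get_polymer())
        if ent is not None and ent.full_sequence:
            seq = "".join(
                three_to_one(gemmi.Entity.first_mon(m)) for m in ent.full_sequence
            )
            if seq:
                out.seqres[ch.name] = seq

    # REMARK 465 — gemmi keeps these as raw text only for PDB input
    for line in text.splitlines():
        if not line.startswith("REMARK 465"):
            continue
        m = _REMARK465_RE.match(line.rstrip())
        if m is None:
            continue
        res_name, chain_id, seq_num = m.group(1), m.group(2), int(m.group(3))
        out.has_remark465 = True
        if chain_filter is not None and chain_id != chain_filter:
            continue
        out.missing_residues.append((chain_id, seq_num, res_name))
    out.missing_residues.sort(key=lambda t: (t[0], t[1]))
    return out


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    for c in name:
        if c.isalpha():
            return c.upper()
    return "C"


def detect_missing(structure: Structure) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive missing residues, as (chain, start, end).

    REMARK 465 records take precedence; numbering-gap inference is used only
    when the file carried no REMARK 465 block at all (mixing the two sources
    would double-count). Gaps that span insertion codes are not inferred as
    missing, because icode regions have irregular numbering.
    """
    runs: list[tuple[str, int, int]] = []
    if structure.has_remark465 or structure.missing_residues:
        by_chain: dict[str, list[int]] = {}
        for chain_id, seq_num, _ in structure.missing_residues:
            by_chain.setdefault(chain_id, []).append(seq_num)
        for chain_id, nums in by_chain.items():
            nums = sorted(set(nums))
            start = prev = nums[0]
            for n in nums[1:]:
                if n == prev + 1:
                    prev = n
                else:
                    runs.append((chain_id, start, prev))
                    start = prev = n
            runs.append((chain_id, start, prev))
    else:
        for chain_id, residues in structure.chains.items():
            poly = [r for r in residues if not r.is_het]
            for a, b in zip(poly, poly[1:]):
                gap = b.seq_num - a.seq_num - 1
                if gap >= 1 and a.icode == "" and b.icode == "":
                    runs.append((chain_id, a.seq_num + 1, b.seq_num - 1))
    runs.sort()
    return runs


def extract_sequence(structure: Structure, chain: str) -> str:
    """One-letter sequence for a chain.

    SEQRES-derived when present; otherwise the resolved residues in order,
    with ``-`` marking each missing residue (from REMARK 465 or gap
    inference). Nonstandard residues with a standard parent map to that
    parent (MSE → M); anything else maps to X.
    """
    if chain in structure.seqres:
        return structure.seqres[chain]
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not in structure {structure.id!r}")
    missing = {
        (c, s, e) for (c, s, e) in detect_missing(structure) if c == chain
    }
    gap_positions = set()
    for _, s, e in missing:
        gap_positions.update(range(s, e + 1))
    parts: list[tuple[int, str]] = []
    for r in structure.chains[chain]:
        if not r.is_het:
            parts.append((r.seq_num, three_to_one(r.res_name)))
    for p in gap_positions:
        parts.append((p, "-"))
    parts.sort()
    return "".join(code for _, code in parts)


def write_pdb(structure: Structure) -> str:
    """Serialize to PDB v3.3 text (REMARK 2/465, SEQRES, ATOM/HETATM)."""
    lines: list[str] = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION.    {structure.resolution:.2f} ANGSTROMS."
        )
    if structure.missing_residues:
        lines.append("REMARK 465")
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for chain_id, seq_num, res_name in sorted(
            structure.missing_residues, key=lambda t: (t[0], t[1])
        ):
            lines.append(f"REMARK 465     {res_name:>3} {chain_id}{seq_num:>6}")
    for chain_id, seq in sorted(structure.seqres.items()):
        three = [_one_to_three(c) for c in seq]
        for i in range(0, len(three), 13):
            chunk = three[i : i + 13]
            lines.append(
                f"SEQRES  {i // 13 + 1:>2} {chain_id} {len(three):>4}  "
                + " ".join(f"{t:>3}" for t in chunk)
            )
    serial = 0
    polymer_then_het = sorted(structure.chains.items())
    for chain_id, residues in polymer_then_het:
        for r in residues:
            record = "HETATM" if r.is_het else "ATOM  "
            for a in r.atoms:
                serial += 1
                x, y, z = a.coords
                if not (-999.999 <= x <= 9999.999 and -999.999 <= y <= 9999.999
                        and -999.999 <= z <= 9999.999):
                    raise ValueError(
                        f"coordinate out of fixed-width PDB range: {a.coords}"
                    )
                name = a.name if len(a.name) == 4 else f" {a.name:<3}"
                lines.append(
                    f"{record}{serial:>5} {name}{'':1}{r.res_name:>3} "
                    f"{chain_id:1}{r.seq_num:>4}{r.icode or '':1}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
                    f"          {a.element:>2}"
                )
        lines.append(f"TER   {serial + 1:>5}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def _one_to_three(code: str) -> str:
    return _ONE_TO_THREE.get(code.upper(), "UNK")
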
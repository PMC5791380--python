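"""Crystallization-environment classification and conformer-pair building.

A conformer is labeled non-aqueous (O) exactly when its crystal contains a
HET group on the organic-solvent lexicon; otherwise aqueous (A). Conformers
of one protein (identical sequence) are paired within matching bound states,
each pair is tagged AA/AO/OO by the two environment labels, and per protein
and subgroup only the pair with the highest Cα RMSD is retained — the
"maximum pair" that summarizes that protein's conformational diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from .model import Structure, WATER_CODES

log = logging.getLogger(__name__)


class Subgroup(str, Enum):
    AA = "AA"
    AO = "AO"
    OO = "OO"


class ConfigError(ValueError):
    pass


def _read_code_list(path_or_text: str | Path) -> set[str]:
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    codes = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if line:
            codes.add(line)
    return codes


def _default_list(name: str) -> set[str]:
    with resources.as_file(resources.files("confdiv.data") / name) as p:
        return _read_code_list(p)


@dataclass
class SolventLexicon:
    """Set of HET codes deemed organic solvents / non-aqueous media."""

    het_codes: set[str] = field(default_factory=set)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.het_codes = {c.upper() for c in self.het_codes}
        bad = [c for c in self.het_codes if len(c) > 3]
        if bad:
            raise ConfigError(f"HET codes longer than 3 characters: {bad}")
        if self.het_codes & WATER_CODES:
            raise ConfigError("water codes cannot be organic solvents")

    @classmethod
    def default(cls) -> "SolventLexicon":
        return cls(het_codes=_default_list("solvents.txt"))

    @classmethod
    def from_file(cls, path: str | Path) -> "SolventLexicon":
        return cls(het_codes=_read_code_list(Path(path)))


def default_additives() -> set[str]:
    """Default exclusion set: ions, buffers, cryoprotectants."""
    return _default_list("additives.txt")


def load_additives(path: str | Path) -> set[str]:
    return _read_code_list(Path(path))


@dataclass
class EnvironmentLabel:
    label: str  # "A" or "O"
    evidence: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        assert (self.label == "O") == bool(self.evidence)


@dataclass
class ConformerPair:
    conf_a: Structure
    conf_b: Structure
    subgroup: Subgroup
    bound_state: str  # "bound-bound" or "unbound-unbound"
    rmsd: float | None = None

    @property
    def ids(self) -> tuple[str, str]:
        return (self.conf_a.id, self.conf_b.id)


def label_environment(structure: Structure, lexicon: SolventLexicon) -> EnvironmentLabel:
    """O iff the structure's HET codes intersect the solvent lexicon."""
    if not lexicon.het_codes:
        raise ConfigError("empty solvent lexicon")
    evidence = set(structure.het_codes) & lexicon.het_codes
    return EnvironmentLabel("O" if evidence else "A", evidence)


def qc_filter(
    structures: list[Structure],
    max_resolution: float = 4.0,
    exclude_mutants: bool = True,
) -> list[Structure]:
    """Keep structures with resolution strictly below the bound, unmutated."""
    kept = []
    for s in structures:
        if s.resolution is None:
            log.warning("%s: no resolution metadata, dropped by QC", s.id)
            continue
        if s.resolution >= max_resolution:
            continue
        if exclude_mutants and s.has_mutations:
            continue
        kept.append(s)
    return kept


def _gap_compatible(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    return all(x == y or x == "-" or y == "-" for x, y in zip(a, b))


def group_by_sequence(structures: list[Structure]) -> list[list[Structure]]:
    """Partition by 100% sequence identity; singletons are discarded.

    Sequences that differ only in missing-residue gap characters (possible
    when SEQRES is absent) belong to the same group: the same protein with
    different disorder must not be split.
    """
    from .io import extract_sequence

    keyed: dict[str, list[Structure]] = {}
    for s in structures:
        chain = next(iter(s.chains))
        seq = extract_sequence(s, chain)
        keyed.setdefault(seq, []).append(s)

    keys = sorted(keyed)
    parent = {k: k for k in keys}

    def find(k: str) -> str:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            if _gap_compatible(ka, kb):
                parent[find(kb)] = find(ka)

    merged: dict[str, list[Structure]] = {}
    for k in keys:
        merged.setdefault(find(k), []).extend(keyed[k])
    groups = [g for g in merged.values() if len(g) >= 2]
    for g in groups:
        g.sort(key=lambda s: s.id)
    return groups


def detect_bound(
    structure: Structure,
    lexicon: SolventLexicon,
    crystallization_additives: set[str] | None = None,
) -> bool:
    """True iff a HET code remains after removing waters, solvents, additives.

    What remains is taken to be a cognate ligand (e.g. GTP with its Mg2+
    excluded as an ion); this separates ligand-driven conformational change
    from the solvent effect under study.
    """
    additives = (
        default_additives() if crystallization_additives is None
        else {c.upper() for c in crystallization_additives}
    )
    for code in structure.het_codes:
        if code in WATER_CODES or code in lexicon.het_codes or code in additives:
            continue
        return True
    return False


def classify_pair(label_a: EnvironmentLabel, label_b: EnvironmentLabel) -> Subgroup:
    n_organic = (label_a.label == "O") + (label_b.label == "O")
    return (Subgroup.AA, Subgroup.AO, Subgroup.OO)[n_organic]


def enumerate_pairs(
    group: list[Structure],
    labels: dict[str, EnvironmentLabel],
    bound_flags: dict[str, bool],
    rmsd_fn=None,
) -> list[ConformerPair]:
    """All unordered same-bound-state pairs in a conformer group.

    ``rmsd_fn(conf_a, conf_b) -> float`` fills the Cα RMSD; by default the
    Kabsch superposition from :mod:`confdiv.superpose` is used. Mixed
    bound/unbound pairs are excluded so ligand effects do not masquerade as
    solvent effects.
    """
    if len(group) < 2:
        raise ValueError("conformer group needs at least 2 structures")
    if rmsd_fn is None:
        from .superpose import pair_rmsd

        rmsd_fn = lambda a, b: pair_rmsd(a, b).rmsd  # noqa: E731

    ordered = sorted(group, key=lambda s: s.id)
    pairs = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if bound_flags[a.id] != bound_flags[b.id]:
                continue
            pairs.append(
                ConformerPair(
                    conf_a=a,
                    conf_b=b,
                    subgroup=classify_pair(labels[a.id], labels[b.id]),
                    bound_state="bound-bound" if bound_flags[a.id] else "unbound-unbound",
                    rmsd=rmsd_fn(a, b),
                )
            )
    return pairs


def select_max_pair(
    pairs: list[ConformerPair], subgroup: Subgroup | str
) -> ConformerPair | None:
    """The pair with maximal RMSD within a subgroup; ties resolved by ids."""
    subgroup = Subgroup(subgroup)
    candidates = [p for p in pairs if p.subgroup == subgroup]
    if not candidates:
        log.info("no %s pair available", subgroup.value)
        return None
    if any(p.rmsd is None for p in candidates):
        raise ValueError("select_max_pair requires rmsd fields populated")
    best = max(p.rmsd for p in candidates)
    tied = [p for p in candidates if p.rmsd == best]
    return min(tied, key=lambda p: (p.conf_a.id, p.conf_b.id))
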
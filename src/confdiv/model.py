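"""In-memory model of a crystallographic structure.

The pipeline works on a deliberately small model: atoms with coordinates,
B-factors and occupancies, residues grouped into chains, plus the pieces of
PDB header metadata the analysis actually consumes — HET residue names
(crystallization-environment evidence), missing-residue records (disorder
evidence), resolution (quality control) and SEQRES (sequence identity).
"""

from __future__ import annotations

import copy
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

WATER_CODES = frozenset({"HOH", "DOD", "WAT"})

#: (chain_id, seq_num, icode) — unique residue address within a structure.
ResKey = tuple[str, int, str]


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    is_het: bool = False
    res_key: ResKey | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.serial}: negative B-factor")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    is_het: bool = False

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_CODES

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """A single-model structure plus the header metadata the pipeline uses."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    seqres: dict[str, str] = field(default_factory=dict)
    missing_residues: list[tuple[str, int, str]] = field(default_factory=list)
    resolution: float | None = None
    has_mutations: bool = False
    # True when missing_residues came from explicit REMARK 465 records
    # (as opposed to being inferable from numbering gaps).
    has_remark465: bool = False

    @property
    def het_codes(self) -> Counter:
        """Multiset of HET residue names, waters excluded."""
        c: Counter = Counter()
        for residues in self.chains.values():
            for r in residues:
                if r.is_het and not r.is_water:
                    c[r.res_name] += 1
        return c

    def polymer_residues(self, chain: str | None = None) -> list[Residue]:
        out = []
        for cid, residues in self.chains.items():
            if chain is not None and cid != chain:
                continue
            out.extend(r for r in residues if not r.is_het)
        return out

    def het_residues(self) -> list[Residue]:
        out = []
        for residues in self.chains.values():
            out.extend(r for r in residues if r.is_het)
        return out

    def atoms(self, include_het: bool = True, include_water: bool = False) -> list[Atom]:
        out = []
        for residues in self.chains.values():
            for r in residues:
                if r.is_water and not include_water:
                    continue
                if r.is_het and not r.is_water and not include_het:
                    continue
                out.extend(r.atoms)
        return out

    def ca_map(self, chain: str | None = None) -> dict[ResKey, np.ndarray]:
        """Cα coordinates keyed by residue address (polymer residues only)."""
        return {
            r.key: r.atom("CA").coords
            for r in self.polymer_residues(chain)
            if r.atom("CA") is not None
        }

    def copy(self) -> "Structure":
        return copy.deepcopy(self)
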
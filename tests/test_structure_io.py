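"""PDB parsing, writing and missing-residue detection."""

import numpy as np
import pytest

from confdiv.io import (
    EmptyStructureError,
    PdbFormatError,
    detect_missing,
    extract_sequence,
    parse_pdb,
    write_pdb,
)

ATOM_LINE = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00"
    "           C"
)


def test_parse_single_atom():
    st = parse_pdb(ATOM_LINE + "\nEND\n")
    atoms = [a for r in st.polymer_residues() for a in r.atoms]
    assert len(atoms) == 1
    assert np.allclose(atoms[0].coords, [1.0, 2.0, 3.0])
    assert atoms[0].bfactor == 10.0
    assert atoms[0].name == "CA"


def test_het_codes_exclude_waters():
    text = (
        "HETATM    1  C1  EOH A 101       9.000   9.000   9.000  1.00 20.00"
        "           C\n"
        "HETATM    2  O   HOH A 201       8.000   8.000   8.000  1.00 30.00"
        "           O\nEND\n"
    )
    st = parse_pdb(text)
    assert set(st.het_codes) == {"EOH"}


def test_remark465_parsing_counts():
    lines = ["REMARK 465 MISSING RESIDUES", "REMARK 465   M RES C SSSEQI"]
    lines += [f"REMARK 465     ALA A{n:>6}" for n in range(30, 41)]
    lines.append(ATOM_LINE)
    st = parse_pdb("\n".join(lines) + "\nEND\n")
    assert len(st.missing_residues) == 11
    assert all(c == "A" for c, _, _ in st.missing_residues)


def test_resolution_parsed():
    text = "REMARK   2 RESOLUTION.    1.80 ANGSTROMS.\n" + ATOM_LINE + "\nEND\n"
    assert parse_pdb(text).resolution == pytest.approx(1.8)


def test_empty_text_and_empty_selection():
    with pytest.raises(PdbFormatError):
        parse_pdb("   \n")
    with pytest.raises(EmptyStructureError):
        parse_pdb(ATOM_LINE + "\nEND\n", chain_filter="Z")


def test_altloc_keeps_highest_occupancy():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00"
        "           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 11.00"
        "           C\nEND\n"
    )
    st = parse_pdb(text)
    atoms = [a for r in st.polymer_residues() for a in r.atoms]
    assert len(atoms) == 1
    assert np.allclose(atoms[0].coords, [5.0, 0.0, 0.0])


class TestDetectMissing:
    def test_remark465_run(self):
        lines = [f"REMARK 465     ALA A{n:>6}" for n in (30, 31, 32, 33, 34)]
        st = parse_pdb("\n".join(lines) + "\n" + ATOM_LINE + "\nEND\n")
        assert detect_missing(st) == [("A", 30, 34)]

    def test_gap_inference(self):
        rows = []
        for i, num in enumerate((44, 45, 46, 52, 53, 54)):
            rows.append(
                f"ATOM  {i + 1:>5}  CA  ALA A{num:>4}    "
                f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            )
        st = parse_pdb("\n".join(rows) + "\nEND\n")
        runs = detect_missing(st)
        assert runs == [("A", 47, 51)]
        assert runs[0][2] - runs[0][1] + 1 == 5  # numbering gap − 1

    def test_fully_resolved(self):
        rows = [
            f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    "
            f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            for i in range(5)
        ]
        assert detect_missing(parse_pdb("\n".join(rows) + "\nEND\n")) == []

    def test_remark465_suppresses_gap_inference(self):
        # REMARK 465 is authoritative; numbering gaps elsewhere are ignored
        rows = ["REMARK 465     ALA A    10"]
        for i, num in enumerate((1, 2, 3, 20, 21)):
            rows.append(
                f"ATOM  {i + 1:>5}  CA  ALA A{num:>4}    "
                f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            )
        assert detect_missing(parse_pdb("\n".join(rows) + "\nEND\n")) == [
            ("A", 10, 10)
        ]

    def test_runs_disjoint_sorted(self):
        nums = [5, 6, 7, 30, 31, 90]
        lines = [f"REMARK 465     ALA A{n:>6}" for n in nums]
        st = parse_pdb("\n".join(lines) + "\n" + ATOM_LINE + "\nEND\n")
        runs = detect_missing(st)
        assert runs == sorted(runs)
        covered = [n for _, s, e in runs for n in range(s, e + 1)]
        assert sorted(covered) == nums and len(set(covered)) == len(covered)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_synthetic_round_trip(self, seed):
        from confdiv.synth import EnsembleSpec, make_study

        spec = EnsembleSpec(seed=seed, missing_regions=[(30, 6, [0])])
        confs, _ = make_study(spec)
        for st in confs:
            rt = parse_pdb(write_pdb(st), id=st.id)
            assert dict(rt.het_codes) == dict(st.het_codes)
            assert detect_missing(rt) == detect_missing(st)
            a_orig = [a for r in st.polymer_residues() for a in r.atoms]
            a_rt = [a for r in rt.polymer_residues() for a in r.atoms]
            assert len(a_orig) == len(a_rt)
            for x, y in zip(a_orig, a_rt):
                assert np.allclose(x.coords, y.coords, atol=1.5e-3)
                assert abs(x.bfactor - y.bfactor) < 0.01

    def test_hetatm_record_emitted(self, small_study):
        confs, _ = small_study
        organic = confs[2]  # o1 carries an injected solvent molecule
        text = write_pdb(organic)
        assert any(line.startswith("HETATM") and "EOH" in line
                   for line in text.splitlines())

    def test_coordinate_overflow_rejected(self, ideal_helix):
        st = ideal_helix.copy()
        st.chains["A"][0].atoms[0].coords = np.array([1e5, 0.0, 0.0])
        with pytest.raises(ValueError, match="range"):
            write_pdb(st)


class TestExtractSequence:
    def test_seqres_priority(self):
        text = "SEQRES   1 A    3  MET ALA GLY\n" + ATOM_LINE + "\nEND\n"
        assert extract_sequence(parse_pdb(text), "A") == "MAG"

    def test_gap_convention_without_seqres(self):
        rows = []
        for i, (num, name) in enumerate([(1, "MET"), (3, "ALA"), (4, "GLY")]):
            rows.append(
                f"ATOM  {i + 1:>5}  CA  {name} A{num:>4}    "
                f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
            )
        assert extract_sequence(parse_pdb("\n".join(rows) + "\nEND\n"), "A") == "M-AG"

    def test_modified_residue_maps_to_parent(self):
        row = (
            "HETATM    1  CA  MSE A   1       0.000   0.000   0.000  1.00 10.00"
            "           C"
        )
        st = parse_pdb(row + "\nEND\n")
        assert extract_sequence(st, "A") == "M"

    def test_unknown_chain(self, ideal_helix):
        with pytest.raises(KeyError):
            extract_sequence(ideal_helix, "Q")
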
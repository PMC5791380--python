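"""Environment labeling, QC, grouping, pairing, maximum-pair selection."""

import pytest

from confdiv.environment import (
    ConfigError,
    ConformerPair,
    SolventLexicon,
    Subgroup,
    classify_pair,
    detect_bound,
    enumerate_pairs,
    group_by_sequence,
    label_environment,
    qc_filter,
    select_max_pair,
)
from confdiv.model import Atom, Residue, Structure


def _structure_with_het(codes, id="x", resolution=2.0):
    st = Structure(id=id, resolution=resolution)
    res = Residue(chain_id="A", seq_num=1, icode="", res_name="ALA")
    res.atoms.append(Atom(serial=1, name="CA", element="C", coords=[0, 0, 0],
                          res_key=res.key))
    st.chains["A"] = [res]
    for i, code in enumerate(codes):
        het = Residue(chain_id="A", seq_num=100 + i, icode="", res_name=code,
                      is_het=True)
        het.atoms.append(Atom(serial=10 + i, name="C", element="C",
                              coords=[10.0 + i, 0, 0], is_het=True,
                              res_key=het.key))
        st.chains["A"].append(het)
    return st


@pytest.fixture(scope="module")
def lexicon():
    return SolventLexicon.default()


class TestLabelEnvironment:
    def test_solvent_hit_is_organic(self, lexicon):
        lab = label_environment(_structure_with_het(["EOH", "SO4"]), lexicon)
        assert lab.label == "O" and lab.evidence == {"EOH"}

    def test_no_het_is_aqueous(self, lexicon):
        assert label_environment(_structure_with_het([]), lexicon).label == "A"

    def test_non_solvent_het_is_aqueous(self, lexicon):
        assert label_environment(_structure_with_het(["SO4"]), lexicon).label == "A"

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ConfigError):
            label_environment(_structure_with_het([]), SolventLexicon(set()))

    def test_water_never_in_lexicon(self):
        with pytest.raises(ConfigError):
            SolventLexicon({"HOH"})


class TestQcFilter:
    def test_strict_resolution_bound(self):
        sts = [_structure_with_het([], id=f"s{i}", resolution=r)
               for i, r in enumerate([1.5, 3.9, 4.0, 4.5])]
        kept = qc_filter(sts, max_resolution=4.0)
        assert [s.resolution for s in kept] == [1.5, 3.9]

    def test_empty_input(self):
        assert qc_filter([]) == []

    def test_mutant_dropped(self):
        st = _structure_with_het([], resolution=1.5)
        st.has_mutations = True
        assert qc_filter([st], exclude_mutants=True) == []
        assert qc_filter([st], exclude_mutants=False) == [st]

    def test_missing_resolution_dropped(self):
        st = _structure_with_het([], resolution=None)
        assert qc_filter([st]) == []


class TestGroupBySequence:
    def _seq_structure(self, id, seq):
        st = Structure(id=id, seqres={"A": seq})
        res = Residue(chain_id="A", seq_num=1, icode="", res_name="ALA")
        res.atoms.append(Atom(serial=1, name="CA", element="C",
                              coords=[0, 0, 0], res_key=res.key))
        st.chains["A"] = [res]
        return st

    def test_partition_drops_singletons(self):
        sts = [self._seq_structure(f"s{i}", s)
               for i, s in enumerate(["MAG", "MAG", "MAG", "MKG"])]
        groups = group_by_sequence(sts)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_all_unique(self):
        sts = [self._seq_structure(f"s{i}", s)
               for i, s in enumerate(["MAG", "MKG", "MCG"])]
        assert group_by_sequence(sts) == []

    def test_gap_characters_ignored_in_identity(self):
        # same protein, different disorder: SEQRES-free sequences with gaps
        from confdiv.io import extract_sequence, parse_pdb

        def atom_rows(nums):
            return "\n".join(
                f"ATOM  {i + 1:>5}  CA  ALA A{num:>4}    "
                f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
                for i, num in enumerate(nums)
            ) + "\nEND\n"

        full = parse_pdb(atom_rows(range(1, 7)), id="full")
        gapped = parse_pdb(atom_rows([1, 2, 3, 5, 6]), id="gapped")
        full.resolution = gapped.resolution = 2.0
        assert extract_sequence(gapped, "A") == "AAA-AA"
        groups = group_by_sequence([full, gapped])
        assert len(groups) == 1 and len(groups[0]) == 2


class TestDetectBound:
    def test_cognate_ligand(self, lexicon):
        st = _structure_with_het(["GTP", "MG"])
        assert detect_bound(st, lexicon) is True  # MG excluded, GTP remains

    def test_solvent_alone_is_unbound(self, lexicon):
        assert detect_bound(_structure_with_het(["EOH"]), lexicon) is False

    def test_no_het_is_unbound(self, lexicon):
        assert detect_bound(_structure_with_het([]), lexicon) is False


class TestClassifyPair:
    def _label(self, which):
        from confdiv.environment import EnvironmentLabel

        return (EnvironmentLabel("O", {"EOH"}) if which == "O"
                else EnvironmentLabel("A", set()))

    @pytest.mark.parametrize("a,b,expected", [
        ("O", "O", Subgroup.OO),
        ("A", "O", Subgroup.AO),
        ("O", "A", Subgroup.AO),
        ("A", "A", Subgroup.AA),
    ])
    def test_mapping(self, a, b, expected):
        assert classify_pair(self._label(a), self._label(b)) == expected

    def test_symmetric(self):
        for a in "AO":
            for b in "AO":
                assert classify_pair(self._label(a), self._label(b)) == \
                    classify_pair(self._label(b), self._label(a))


class TestEnumeratePairs:
    def _group(self, n, het_per_conf):
        sts = [_structure_with_het(het_per_conf[i], id=f"c{i}")
               for i in range(n)]
        lex = SolventLexicon.default()
        labels = {s.id: label_environment(s, lex) for s in sts}
        bound = {s.id: detect_bound(s, lex) for s in sts}
        return sts, labels, bound

    def test_all_unbound_pairs(self):
        sts, labels, bound = self._group(3, [[], [], []])
        pairs = enumerate_pairs(sts, labels, bound, rmsd_fn=lambda a, b: 1.0)
        assert len(pairs) == 3

    def test_mixed_bound_states_excluded(self):
        sts, labels, bound = self._group(3, [["GTP"], ["GTP"], []])
        pairs = enumerate_pairs(sts, labels, bound, rmsd_fn=lambda a, b: 1.0)
        assert len(pairs) == 1
        assert pairs[0].bound_state == "bound-bound"

    def test_one_bound_one_unbound(self):
        sts, labels, bound = self._group(2, [["GTP"], []])
        assert enumerate_pairs(sts, labels, bound,
                               rmsd_fn=lambda a, b: 1.0) == []


class TestSelectMaxPair:
    def _pair(self, ida, idb, rmsd, sg=Subgroup.AA):
        return ConformerPair(Structure(id=ida), Structure(id=idb), sg,
                             "unbound-unbound", rmsd)

    def test_maximum_selected(self):
        pairs = [self._pair("a", "b", 0.3), self._pair("a", "c", 0.9),
                 self._pair("b", "c", 0.5)]
        assert select_max_pair(pairs, "AA").rmsd == 0.9

    def test_single_pair(self):
        p = self._pair("a", "b", 0.1)
        assert select_max_pair([p], "AA") is p

    def test_tie_break_lexicographic(self):
        pairs = [self._pair("a2", "b", 0.7), self._pair("a1", "b", 0.7)]
        assert select_max_pair(pairs, "AA").conf_a.id == "a1"

    def test_absent_subgroup(self):
        assert select_max_pair([self._pair("a", "b", 0.3)], "OO") is None


def test_metamorphic_solvent_injection_flips_subgroup(small_study):
    """Injecting a lexicon solvent into an A conformer moves AA pairs to AO."""
    from confdiv.synth import inject_het

    confs, _ = small_study
    lex = SolventLexicon.default()
    a1, a2 = confs[0], confs[1]
    assert label_environment(a1, lex).label == "A"
    before = classify_pair(label_environment(a1, lex), label_environment(a2, lex))
    assert before == Subgroup.AA

    a1_spiked = inject_het(a1, "DMF", n_copies=1)
    lab = label_environment(a1_spiked, lex)
    assert lab.label == "O" and "DMF" in lab.evidence
    after = classify_pair(lab, label_environment(a2, lex))
    assert after == Subgroup.AO
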
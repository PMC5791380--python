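"""Radius of gyration, IDR rules, active-site metrics, pair deltas."""

import numpy as np
import pytest

from confdiv.metrics import (
    IdrSet,
    active_site_metrics,
    find_idrs,
    pair_deltas,
    radius_of_gyration,
)
from confdiv.model import Atom, Residue, Structure
from confdiv.sasa import AsaRecord
from confdiv.superpose import PairRmsd


def _point_structure(coords, element="C"):
    st = Structure(id="pts")
    res = Residue(chain_id="A", seq_num=1, icode="", res_name="GLY")
    for i, c in enumerate(coords):
        res.atoms.append(Atom(serial=i + 1, name=f"C{i}", element=element,
                              coords=c, res_key=res.key))
    st.chains["A"] = [res]
    return st


class TestRadiusOfGyration:
    def test_single_atom(self):
        assert radius_of_gyration(
            _point_structure([[1.0, 2.0, 3.0]])
        ) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses(self):
        st = _point_structure([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(st) == pytest.approx(1.0)

    def test_unit_cube_corners(self):
        corners = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        st = _point_structure(corners)
        assert radius_of_gyration(st) == pytest.approx(np.sqrt(3) / 2)

    def test_no_atoms_error(self):
        with pytest.raises(ValueError):
            radius_of_gyration(Structure(id="empty", chains={"A": []}))


def _chain_with_missing(n_residues, missing, offset=1, seqres=True):
    """Chain of Cα residues numbered offset..offset+n−1 with a missing set."""
    st = Structure(id="idr")
    if seqres:
        st.seqres["A"] = "A" * n_residues
    residues = []
    for i in range(n_residues):
        num = offset + i
        if num in missing:
            st.missing_residues.append(("A", num, "ALA"))
            continue
        r = Residue(chain_id="A", seq_num=num, icode="", res_name="ALA")
        r.atoms.append(Atom(serial=i + 1, name="CA", element="C",
                            coords=[float(i) * 3.8, 0, 0], res_key=r.key))
        residues.append(r)
    st.chains["A"] = residues
    st.has_remark465 = bool(st.missing_residues)
    return st


class TestFindIdrs:
    """The disorder-region rule: ≥5 consecutive missing, termini excluded."""

    def test_run_of_four_rejected(self):
        st = _chain_with_missing(200, set(range(50, 54)))
        out = find_idrs(st)
        assert out.n_regions == 0
        assert out.n_missing_residues == 4

    def test_run_of_five_accepted(self):
        out = find_idrs(_chain_with_missing(200, set(range(50, 55))))
        assert out.n_regions == 1
        assert out.regions[0] == ("A", 50, 54, 5)

    def test_terminal_run_clipped_to_nothing(self):
        # run 15–24: clipped to 21–24, length 4 < 5
        out = find_idrs(_chain_with_missing(200, set(range(15, 25))))
        assert out.n_regions == 0
        assert out.n_missing_residues == 10

    def test_terminal_run_surviving_clip(self):
        # run 15–26: clipped to 21–26, length 6 ≥ 5
        out = find_idrs(_chain_with_missing(200, set(range(15, 27))))
        assert out.n_regions == 1
        assert out.regions[0] == ("A", 21, 26, 6)

    def test_c_terminal_exclusion(self):
        # run 176–185 in a 200-chain: allowed tail ends at 180 → clipped len 5
        out = find_idrs(_chain_with_missing(200, set(range(176, 186))))
        assert out.n_regions == 1
        assert out.regions[0] == ("A", 176, 180, 5)

    def test_renumbering_offset_invariance(self):
        base = find_idrs(_chain_with_missing(200, set(range(50, 56))))
        shifted = find_idrs(
            _chain_with_missing(200, set(range(150, 156)), offset=101)
        )
        assert base.n_regions == shifted.n_regions == 1
        assert base.regions[0][3] == shifted.regions[0][3] == 6

    def test_gap_inference_source(self):
        st = _chain_with_missing(200, set(range(50, 56)), seqres=False)
        st.missing_residues = []
        st.has_remark465 = False  # fall back to numbering-gap inference
        out = find_idrs(st)
        assert out.n_regions == 1 and out.regions[0][3] == 6

    def test_fully_resolved(self):
        out = find_idrs(_chain_with_missing(100, set()))
        assert out == IdrSet(regions=[], n_regions=0, n_missing_residues=0)


def _asa_record(rels):
    return AsaRecord(per_atom=np.array([]), per_residue_abs={},
                     per_residue_rel=rels, global_abs=0.0, global_rel=0.0,
                     buried_fraction=None)


class TestActiveSiteMetrics:
    def _pair(self, devs):
        keys = [("A", i + 1, "") for i in range(len(devs))]
        arr = np.asarray(devs, float)
        return PairRmsd(float(np.sqrt(np.mean(arr**2))), arr, keys)

    def test_unmoved_site(self):
        pr = self._pair([0.0, 0.0, 0.8])
        out = active_site_metrics(pr, _asa_record({}), _asa_record({}),
                                  [("A", 1), ("A", 2)])
        assert out["site_rmsd"] == pytest.approx(0.0)

    def test_site_mean(self):
        pr = self._pair([0.2, 0.6, 3.0])
        out = active_site_metrics(pr, _asa_record({}), _asa_record({}),
                                  [("A", 1), ("A", 2)])
        assert out["site_rmsd"] == pytest.approx(0.4)

    def test_rel_asa_shift_as_fraction(self):
        pr = self._pair([0.1, 0.1])
        rels_a = {("A", 1, ""): 30.0, ("A", 2, ""): 50.0}
        rels_b = {("A", 1, ""): 36.0, ("A", 2, ""): 40.0}
        out = active_site_metrics(pr, _asa_record(rels_a), _asa_record(rels_b),
                                  [("A", 1), ("A", 2)])
        assert out["site_rel_asa_diff"] == pytest.approx(0.08)  # mean(6,10)/100

    def test_unresolved_site_absent(self):
        pr = self._pair([0.1, 0.1])
        out = active_site_metrics(pr, _asa_record({}), _asa_record({}),
                                  [("B", 99)])
        assert out["site_rmsd"] is None

    def test_site_only_perturbation_exceeds_global(self):
        from confdiv.superpose import pair_rmsd
        from confdiv.synth import EnsembleSpec, build_backbone, perturb_to_rmsd

        base = build_backbone(EnsembleSpec(seed=13))
        site = [("A", n) for n in range(25, 30)]
        pert = perturb_to_rmsd(base, 0.4, mode="site-only", seed=2,
                               site_residues=site)
        pr = pair_rmsd(base, pert)
        out = active_site_metrics(pr, _asa_record({}), _asa_record({}), site)
        assert out["site_rmsd"] > pr.rmsd


class TestPairDeltas:
    def _panel(self, global_abs=5000.0, n_regions=1, n_missing=0, hbonds=40,
               rg=12.0):
        from confdiv.metrics import MetricPanel
        from confdiv.secondary import SsString

        rec = _asa_record({})
        rec.global_abs = global_abs
        rec.global_rel = global_abs / 2
        return MetricPanel(structure_id="x", asa=rec, rg=rg, n_hbonds=hbonds,
                           ss=SsString("", []),
                           idrs=IdrSet([], n_regions, n_missing),
                           seq_length=100)

    def test_identical_panels(self):
        d = pair_deltas(self._panel(), self._panel())
        assert d.d_global_asa == 0 and d.d_hbonds == 0 and d.d_rg == 0

    def test_asa_difference(self):
        d = pair_deltas(self._panel(5000.0), self._panel(5310.76))
        assert d.d_global_asa == pytest.approx(310.76)

    def test_region_and_missing_fraction(self):
        d = pair_deltas(self._panel(n_regions=2, n_missing=6),
                        self._panel(n_regions=1, n_missing=0))
        assert d.d_n_idr_regions == 1
        assert d.d_missing_fraction == pytest.approx(0.06)
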
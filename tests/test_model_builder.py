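"""Geometry of the idealized helices, bundle and assembled dimer."""

import numpy as np
import pytest

from jiptandem import model_builder as mb
from jiptandem import synthetic_data as sd
from jiptandem.sequence_features import RegionAnnotation, SequenceRecord, extract_region


def seq(n, first=1):
    return SequenceRecord(id=f"poly{n}", residues="A" * n, first_residue_number=first)


class TestIdealHelix:
    def test_axial_extent(self):
        h = mb.build_ideal_helix(seq(10))
        assert mb.axial_length(h) == pytest.approx(13.5, abs=0.5)

    def test_single_residue_at_origin(self):
        h = mb.build_ideal_helix(seq(1), origin=(0, 0, 0))
        assert len(h) == 1
        assert np.linalg.norm(h.xyz[0]) <= 2.5  # on the helix cylinder

    def test_calpha_spacing(self):
        h = mb.build_ideal_helix(seq(30))
        d = np.linalg.norm(np.diff(h.xyz, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            mb.build_ideal_helix(seq(5), axis=(0, 0, 0))


class TestCoiledCoil:
    def test_lzi_axial_length(self, jip3):
        lzi = extract_region(jip3, RegionAnnotation("LZI", 74, 177))
        cc = mb.build_parallel_dimer_cc(lzi)
        assert mb.axial_length(cc) == pytest.approx(150.0, abs=8.0)

    def test_short_coil_length(self):
        # for a stub this short the principal axis is ambiguous, so measure
        # the extent along the construction (z) axis: (n-1) x rise
        cc = mb.build_parallel_dimer_cc(seq(8))
        z = cc.xyz[:, 2]
        assert z.max() - z.min() == pytest.approx(10.4, abs=1.0)

    def test_knob_packing_distance(self, jip3):
        """Inter-chain Calpha distances at heptad a/d core positions."""
        from jiptandem.sequence_features import assign_heptad_register, best_heptad_phase

        lzi = extract_region(jip3, RegionAnnotation("LZI", 74, 177))
        phase, _ = best_heptad_phase(lzi)
        reg = assign_heptad_register(lzi, phase)
        cc = mb.build_parallel_dimer_cc(
            lzi, mb.CrickParameters(register_phase=phase))
        a = cc.select(chain="A").sorted_by_chain().xyz
        b = cc.select(chain="B").sorted_by_chain().xyz
        core = [i for i, r in enumerate(reg) if r in "ad"]
        dists = np.linalg.norm(a[core] - b[core], axis=1)
        assert np.all(dists >= 5.0) and np.all(dists <= 7.5)

    def test_length_linear_in_residues(self):
        p = mb.CrickParameters()
        for n in (21, 35, 70):
            l1 = mb.axial_length(mb.build_parallel_dimer_cc(seq(n), p))
            l0 = mb.axial_length(mb.build_parallel_dimer_cc(seq(n - 7), p))
            assert l1 - l0 == pytest.approx(7 * p.rise_per_residue_axial, abs=0.2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mb.build_parallel_dimer_cc(seq(5))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mb.CrickParameters(superhelix_radius=-1.0)


@pytest.fixture(scope="module")
def bundle(jip3):
    return mb.build_rh1_dimer(
        extract_region(jip3, RegionAnnotation("a1", 26, 43)),
        extract_region(jip3, RegionAnnotation("a2", 50, 73)),
        extract_region(jip3, RegionAnnotation("loop", 44, 49)))


class TestBundle:
    def test_bundle_length(self, bundle):
        assert mb.axial_length(bundle) == pytest.approx(40.0, abs=4.0)

    def test_chain_residue_census(self, bundle):
        for ch in "AB":
            nums = sorted(bundle.select(chain=ch).resnum.tolist())
            assert nums == list(range(26, 74))

    def test_helices_antiparallel(self, bundle):
        from jiptandem.model_builder import principal_axis

        a1 = bundle.select(chain="A", resrange=(26, 43))
        a2 = bundle.select(chain="A", resrange=(50, 73))

        def raw_axis(s):
            x = s.xyz - s.xyz.mean(axis=0)
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            # orient along the chain direction (first -> last residue)
            v = vt[0]
            return v if v @ (s.xyz[-1] - s.xyz[0]) > 0 else -v

        assert raw_axis(a1) @ raw_axis(a2) < -0.9


class TestAssembly:
    def test_overall_dimensions(self, model):
        assert mb.max_extent(model) == pytest.approx(210.0, abs=10.0)
        assert mb.thickness(model) == pytest.approx(20.0, abs=3.0)

    def test_lzi_length_in_context(self, model):
        assert mb.axial_length(model, (74, 177)) == pytest.approx(150.0, abs=8.0)

    def test_chain_numbering_contiguous(self, model):
        for ch in "AB":
            nums = model.select(chain=ch).sorted_by_chain().resnum
            assert nums[0] == 19 and nums[-1] == 187
            assert np.all(np.diff(nums) == 1)

    def test_coordinate_rg_of_rod(self, model):
        # rod estimate: Rg^2 ~ L^2/12 + R^2/2 with L~210, R~10
        assert 61.0 <= mb.radius_of_gyration(model) <= 66.0

    def test_two_fold_symmetry(self, model):
        assert mb.chain_symmetry_rmsd(model) < 0.1

    def test_bundle_axis_collinear_with_coil(self, model):
        from jiptandem.refinement import hinge_angle

        assert hinge_angle(model) < 15.0

    def test_helical_calpha_spacing(self, model):
        for ch in "AB":
            for rng in ((26, 43), (50, 73), (74, 187)):
                xyz = model.select(chain=ch, resrange=rng).sorted_by_chain().xyz
                d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
                assert np.all(d >= 3.6) and np.all(d <= 4.0)

    def test_no_close_contacts(self, model):
        model.validate(min_separation=1.0)

    def test_segment_gap_rejected(self, construct):
        with pytest.raises(ValueError):
            mb.assemble_rh1_lzi_dimer(construct,
                                      segments={"alpha1": (27, 43)})


class TestMeasures:
    def test_axial_and_extent_basics(self):
        two = mb.Structure(np.array(["A", "A"]), np.array([1, 2]),
                           np.array(["ALA", "ALA"]), np.array(["CA", "CA"]),
                           np.array([[0.0, 0, 0], [0, 0, 10.0]]))
        assert mb.axial_length(two) == pytest.approx(10.0)
        one = two.select(resrange=(1, 1))
        assert mb.axial_length(one) == 0.0
        assert mb.max_extent(two) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            mb.max_extent(one)

    def test_extent_bounds_axial(self, model):
        assert mb.max_extent(model) >= mb.axial_length(model)


class TestPdbIO:
    def test_round_trip(self, model, tmp_path):
        p = tmp_path / "model.pdb"
        mb.write_pdb(model, p)
        back = mb.read_pdb(p)
        a = model.sorted_by_chain()
        b = back.sorted_by_chain()
        assert np.array_equal(a.chain, b.chain)
        assert np.array_equal(a.resnum, b.resnum)
        assert np.allclose(a.xyz, b.xyz, atol=1e-3)

    def test_fixed_column_format(self, model, tmp_path):
        p = tmp_path / "model.pdb"
        mb.write_pdb(model, p)
        lines = [l for l in p.read_text().splitlines() if l.startswith("ATOM")]
        assert lines
        for l in lines[:10]:
            assert l[12:16].strip() == "CA"
            assert l[21] in "AB"
            float(l[30:38]), float(l[38:46]), float(l[46:54])  # coordinate columns

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            mb.read_pdb(p)


class TestDecoys:
    def test_bend_zero_is_identity(self, model):
        d = sd.make_decoys(model, bend_angles_deg=(0.0,))[0]
        assert np.allclose(np.sort(d.xyz, axis=0), np.sort(model.xyz, axis=0))

    def test_extent_decreases_with_bend(self, model):
        decoys = sd.make_decoys(model, bend_angles_deg=(10, 20, 30))
        ext = [mb.max_extent(d) for d in decoys]
        assert ext[0] > ext[1] > ext[2]

    def test_hinge_angles_realized(self, model):
        from jiptandem.refinement import hinge_angle

        for ang, d in zip((10, 20, 30), sd.make_decoys(model)):
            assert hinge_angle(d) == pytest.approx(ang, abs=2.0)
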
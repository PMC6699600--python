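import numpy as np
import pytest

from porescope.centerline import Profile, fit_centerline, uniform_grid
from porescope.hydrophobicity import (
    BUNDLED_SCALES,
    ResidueAnnotation,
    annotation_map,
    classify_residues,
    dewetting_free_energy,
    hydrophobicity_profile,
    load_scale,
    normalize_scale,
)

from .conftest import make_straight_trace
from .test_structure_io import make_frame


def flat_radius(lo=-2.0, hi=2.0, value=0.38):
    s = uniform_grid(lo, hi, 0.1)
    return Profile(s=s, values=np.full(len(s), value), quantity="radius")


def annotation(s_cog=0.0, h=0.5, facing=1.0, lining=1.0):
    return ResidueAnnotation(chain="A", residue_id=1, residue_name="LEU",
                             s_cog=s_cog, rho_cog=0.5, s_alpha=s_cog, rho_alpha=0.6,
                             pore_lining=lining, pore_facing=facing, hydrophobicity=h)


class TestNormalizeScale:
    def test_two_sided_rescale(self):
        scale = normalize_scale({"A": 2.0, "B": -4.0, "C": 0.0})
        assert scale.normalized == {"A": 1.0, "B": -1.0, "C": 0.0}

    def test_orientation_flip_for_transfer_free_energies(self):
        # negative = hydrophobic in free-energy-of-transfer scales
        scale = normalize_scale({"TRP": -1.85, "GLU": 2.02, "GLY": 0.0},
                                higher_is_hydrophobic=False)
        assert scale["TRP"] == pytest.approx(1.0)
        assert scale["GLU"] == pytest.approx(-1.0)
        assert scale["GLY"] == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_scale({"A": 0.0, "B": 0.0})

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_scale({})

    @pytest.mark.parametrize("name", BUNDLED_SCALES)
    def test_bundled_scales_span_unit_interval(self, name):
        scale = load_scale(name)
        values = np.array(list(scale.normalized.values()))
        assert len(values) == 20
        assert values.max() == pytest.approx(1.0)
        assert values.min() == pytest.approx(-1.0)
        assert np.all((-1.0 <= values) & (values <= 1.0))

    @pytest.mark.parametrize("name", BUNDLED_SCALES)
    def test_bundled_scales_preserve_natural_zero(self, name):
        scale = load_scale(name)
        higher = name == "kyte-doolittle"
        for res, raw in scale.raw.items():
            oriented = raw if higher else -raw
            assert np.sign(scale.normalized[res]) == np.sign(oriented)

    def test_unknown_scale_raises(self):
        with pytest.raises(FileNotFoundError, match="bundled scales"):
            load_scale("no-such-scale")

    def test_custom_scale_file(self, tmp_path):
        path = tmp_path / "custom.tsv"
        path.write_text("# higher_is_hydrophobic: true\nALA 1.0\nGLY -2.0\n")
        scale = load_scale(str(path))
        assert scale["ALA"] == 1.0
        assert scale["GLY"] == -1.0


@pytest.fixture(scope="module")
def straight_spline():
    return fit_centerline(make_straight_trace(-2.0, 2.0, 0.1))


class TestClassifyResidues:
    def _frame_with_residue(self, rho_ca, rho_cb, z=0.0):
        return make_frame([[rho_ca, 0.0, z], [rho_cb, 0.0, z]],
                          names=["CA", "CB"], res_ids=[1, 1])

    def test_boundary_inclusive_lining(self, straight_spline):
        # rho_cog exactly R + R_thres -> pore-lining
        rho = 0.38 + 0.75
        frame = self._frame_with_residue(rho, rho)
        ann = classify_residues(frame, straight_spline, flat_radius(), r_thres=0.75)
        assert ann[0].pore_lining == 1.0

    def test_just_outside_cutoff_not_lining(self, straight_spline):
        rho = 0.38 + 0.75 + 1e-3
        frame = self._frame_with_residue(rho, rho)
        ann = classify_residues(frame, straight_spline, flat_radius(), r_thres=0.75)
        assert ann[0].pore_lining == 0.0

    def test_boundary_inclusive_facing(self, straight_spline):
        # rho_alpha == rho_cog (fully extended radial) -> pore-facing
        frame = self._frame_with_residue(0.5, 0.5)
        ann = classify_residues(frame, straight_spline, flat_radius())
        assert ann[0].pore_facing == 1.0

    def test_outward_side_chain_not_facing(self, straight_spline):
        frame = self._frame_with_residue(0.5, 0.9)
        ann = classify_residues(frame, straight_spline, flat_radius())
        assert ann[0].pore_lining == 1.0
        assert ann[0].pore_facing == 0.0

    def test_missing_alpha_carbon_excluded_with_warning(self, straight_spline):
        frame = make_frame([[0.5, 0.0, 0.0]], names=["P"], res_names=["DUM"])
        with pytest.warns(UserWarning, match="alpha-carbon"):
            ann = classify_residues(frame, straight_spline, flat_radius())
        assert ann == []

    def test_fixture_ground_truth(self, classification_pore, classification_analysis):
        frame, _, truth = classification_pore
        with pytest.warns(UserWarning, match="alpha-carbon"):
            ann = classify_residues(frame, classification_analysis["spline"],
                                    classification_analysis["radius"], r_thres=0.75)
        facing = {a.key for a in ann if a.pore_facing > 0}
        lining = {a.key for a in ann if a.pore_lining > 0}
        assert facing == truth.facing
        assert lining == truth.lining

    def test_facing_implies_lining(self, classification_pore, classification_analysis):
        frame, _, _ = classification_pore
        with pytest.warns(UserWarning):
            ann = classify_residues(frame, classification_analysis["spline"],
                                    classification_analysis["radius"])
        assert all(a.pore_lining >= a.pore_facing for a in ann)

    def test_order_independent(self, straight_spline):
        frame = make_frame(
            [[0.5, 0.0, 0.0], [0.6, 0.0, 0.0], [0.0, 1.4, 0.5], [0.0, 1.5, 0.5]],
            names=["CA", "CB", "CA", "CB"], res_ids=[1, 1, 2, 2])
        fwd = classify_residues(frame, straight_spline, flat_radius())
        rev = classify_residues(frame.subset(np.array([3, 2, 1, 0])), straight_spline, flat_radius())
        by_key = lambda anns: {a.key: (a.pore_lining, a.pore_facing) for a in anns}
        assert by_key(fwd) == by_key(rev)

    def test_hydrophobicity_attached_from_scale(self, straight_spline):
        frame = self._frame_with_residue(0.5, 0.5)
        frame.res_names[:] = "TRP"
        scale = load_scale("wimley-white-interface")
        ann = classify_residues(frame, straight_spline, flat_radius(), scale=scale)
        assert ann[0].hydrophobicity == pytest.approx(1.0)

    def test_annotation_map_format(self):
        anns = [annotation()]
        assert annotation_map(anns) == {("A", 1): (1.0, 1.0)}


class TestHydrophobicityProfile:
    grid = uniform_grid(-2.0, 2.0, 0.05)

    def test_single_residue_peak(self):
        profile = hydrophobicity_profile([annotation(s_cog=0.0, h=0.8)], self.grid)
        at_res = profile.values[np.argmin(np.abs(profile.s))]
        assert at_res == pytest.approx(0.8, abs=0.02)
        assert profile.values[0] < at_res  # decays away from the residue

    def test_constant_values_average_to_constant(self):
        anns = [annotation(s_cog=s, h=0.4) for s in np.arange(-1, 1.01, 0.2)]
        profile = hydrophobicity_profile(anns, self.grid)
        near = np.abs(profile.s) < 0.8
        np.testing.assert_allclose(profile.values[near], 0.4, atol=0.01)

    def test_antisymmetric_pair_cancels_midway(self):
        anns = [annotation(s_cog=0.0, h=1.0), annotation(s_cog=1.0, h=-1.0)]
        profile = hydrophobicity_profile(anns, uniform_grid(-1.0, 2.0, 0.25))
        mid = profile.values[np.argmin(np.abs(profile.s - 0.5))]
        assert mid == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_residue_values_near_residues(self):
        rng = np.random.default_rng(0)
        h_vals = rng.uniform(-1, 1, 9)
        anns = [annotation(s_cog=s, h=h) for s, h in zip(np.linspace(-1, 1, 9), h_vals)]
        profile = hydrophobicity_profile(anns, self.grid)
        near = np.abs(profile.s) <= 1.0
        assert profile.values[near].max() <= h_vals.max() + 1e-12
        assert profile.values[near].min() >= h_vals.min() - 1e-12

    def test_decays_to_zero_far_from_residues(self):
        profile = hydrophobicity_profile([annotation(s_cog=0.0, h=1.0)],
                                         uniform_grid(-3.0, 3.0, 0.1))
        far = np.abs(profile.s) > 1.5  # beyond ~6 smoothing spans
        assert np.abs(profile.values[far]).max() < 0.05

    def test_span_does_not_change_sign_pattern(self, classification_pore, classification_analysis):
        frame, _, _ = classification_pore
        with pytest.warns(UserWarning):
            anns = classify_residues(frame, classification_analysis["spline"],
                                     classification_analysis["radius"],
                                     scale=load_scale("wimley-white-interface"))
        grid = uniform_grid(-1.0, 1.0, 0.1)
        signs = []
        for span in [0.1, 0.225, 0.5]:
            profile = hydrophobicity_profile(anns, grid, smoothing_span=span)
            center = profile.values[np.abs(profile.s) < 0.4]
            edge = profile.values[np.abs(profile.s) > 0.9]
            signs.append((np.sign(center.mean()), np.sign(edge.mean())))
        assert signs == [(1.0, -1.0)] * 3  # hydrophobic center, hydrophilic rim

    def test_no_facing_residues_raises(self):
        with pytest.raises(ValueError, match="pore-facing"):
            hydrophobicity_profile([annotation(facing=0.0)], self.grid)

    def test_bad_span_raises(self):
        with pytest.raises(ValueError, match="span"):
            hydrophobicity_profile([annotation()], self.grid, smoothing_span=0.0)


class TestDewettingFreeEnergy:
    def test_right_angle_contact_is_length_independent(self):
        r, gamma = 0.4, 0.05
        for length in [0.5, 1.0, 7.0]:
            assert dewetting_free_energy(r, length, gamma, np.pi / 2) == pytest.approx(
                2 * np.pi * r**2 * gamma)

    def test_hydrophilic_pore_grows_linearly_with_length(self):
        vals = [dewetting_free_energy(0.4, length, 0.05, 0.0) for length in [1.0, 2.0, 3.0]]
        diffs = np.diff(vals)
        assert np.all(vals[0] > 0)
        assert diffs[0] == pytest.approx(diffs[1])

    def test_direct_formula_evaluation(self):
        r, length, gamma, theta = 0.5, 1.0, 0.05, 2 * np.pi / 3
        expected = 2 * np.pi * r * gamma * (r + length * np.cos(theta))
        assert dewetting_free_energy(r, length, gamma, theta) == pytest.approx(expected)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            dewetting_free_energy(-0.1, 1.0, 0.05, 0.0)
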
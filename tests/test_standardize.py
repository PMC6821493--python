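"""Tests of segmentation, reorientation, template and enrichment math."""

import dataclasses

import numpy as np
import pytest

from synapsequant.pipeline import find_cell_seed
from synapsequant.standardize import (EnrichmentRegion, NoCellCoupleError,
                                      StandardizedCell, SynapseAnnotation,
                                      TruncatedCellWarning, build_template,
                                      compute_enrichment_region, detect_tight_coupling,
                                      enrichment, reorient_interface_up, segment_t_cell,
                                      standardize_shape)
from synapsequant.synthgen import PatternScript, SimConfig, make_cell_couple

SPACING = (1.0, 0.34, 0.34)


class TestDetectTightCoupling:
    def test_instant_full_width(self):
        assert detect_tight_coupling([0, 0, 3, 3, 3, 3, 3, 3]) == 2

    def test_forty_second_rule_wins(self):
        widths = [0, 1, 1.5, 2, 3, 3, 3, 3, 3, 3, 3, 3]
        # full width (>= 0.9 x steady 3.0) reached at frame 4; first contact
        # at frame 1 plus two frames (40 s) gives 3, which is earlier
        assert detect_tight_coupling(widths) == 3

    def test_no_contact_raises(self):
        with pytest.raises(NoCellCoupleError):
            detect_tight_coupling([0.0] * 10)


class TestSegmentTCell:
    def _sphere(self, radius_um=4.0, value=100.0, shape=(13, 41, 41)):
        sp = np.asarray(SPACING)
        axes = [np.arange(n) * s for n, s in zip(shape, sp)]
        Z, Y, X = np.meshgrid(*axes, indexing="ij")
        c = sp * (np.asarray(shape) - 1) / 2
        inside = (Z - c[0]) ** 2 + (Y - c[1]) ** 2 + (X - c[2]) ** 2 <= radius_um ** 2
        return np.where(inside, value, 0.0), inside, tuple((np.asarray(shape) - 1) // 2)

    def test_sphere_volume_within_5_percent(self):
        vol, inside, center = self._sphere()
        mask = segment_t_cell(vol, center, SPACING)
        analytic = 4 / 3 * np.pi * 4.0 ** 3
        measured = mask.sum() * np.prod(SPACING)
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_seed_in_background_raises(self):
        vol, _, _ = self._sphere()
        with pytest.raises(ValueError, match="background"):
            segment_t_cell(vol, (0, 0, 0), SPACING)

    def test_second_cell_excluded_by_connectivity(self):
        vol, inside, center = self._sphere(radius_um=3.0, shape=(13, 71, 41))
        other = np.zeros_like(vol, dtype=bool)
        other[4:9, 55:68, 10:30] = True
        vol[other] = 100.0
        mask = segment_t_cell(vol, center, SPACING)
        assert not np.any(mask & other)
        assert mask[center]

    def test_truncated_cell_warns(self):
        vol, _, center = self._sphere(radius_um=6.0, shape=(9, 41, 41))
        with pytest.warns(TruncatedCellWarning):
            segment_t_cell(vol, center, SPACING)


class TestReorient:
    def _couple(self, normal=None):
        cfg = SimConfig(n_frames=1, poisson_scale=0, gaussian_sd=0,
                        accumulation_contrast=3.0)
        series, truth = make_cell_couple(cfg, PatternScript.uniform("central", 1),
                                         interface_normal=normal)
        ann = SynapseAnnotation(
            0, tuple(truth.interface_center_um),
            tuple(truth.interface_center_um + truth.axis_into_cell * 8.0))
        return series.data[0], truth, ann

    def test_aligned_cell_identity(self):
        vol, truth, ann = self._couple()
        out = reorient_interface_up(vol, truth.cell_mask, ann, SPACING)
        assert out.rotation_deg == pytest.approx(0.0, abs=1e-6)
        assert np.array_equal(out.mask, truth.cell_mask)
        assert np.allclose(out.volume[truth.cell_mask], vol[truth.cell_mask])

    def test_lateral_cell_rotated_interface_on_top(self):
        vol, truth, ann = self._couple(normal=(0.0, -1.0, 0.0))
        out = reorient_interface_up(vol, truth.cell_mask, ann, SPACING)
        assert out.rotation_deg == pytest.approx(90.0, abs=1e-6)
        zs = np.flatnonzero(out.mask.any(axis=(1, 2)))
        # the rotated interface-center z sits at the top of the mask
        assert abs(out.interface_center_um[0] / SPACING[0] - zs[0]) <= 1.5

    def test_masked_intensity_conserved_within_1_percent(self):
        vol, truth, ann = self._couple(normal=(0.0, -0.6, 0.8))
        out = reorient_interface_up(vol, truth.cell_mask, ann, SPACING)
        before = vol[truth.cell_mask].sum()
        after = out.volume[out.mask].sum()
        assert after == pytest.approx(before, rel=0.01)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SynapseAnnotation(0, (1, 1, 1), (1, 1, 1))


class TestTemplate:
    def test_exact_voxel_count(self, template):
        assert template.n_voxels == 6628
        assert template.mask.sum() == 6628
        assert len(template.centers_um) == 6628

    def test_coarser_grid_fewer_voxels(self, template):
        a, c = template.lateral_semi_axis, template.axial_semi_axis
        dz, dy, dx = (2 * s for s in template.spacing)
        depths = (np.arange(int(np.ceil(c / dz))) + 0.5) * dz
        ys = np.arange(-int(np.ceil(a / dy)), int(np.ceil(a / dy)) + 1) * dy
        D, Y, X = np.meshgrid(depths, ys, ys, indexing="ij")
        count = int(((X ** 2 + Y ** 2) / a ** 2 + D ** 2 / c ** 2 <= 1).sum())
        assert count < template.n_voxels

    def test_rotational_symmetry(self, template):
        flipped = template.mask[:, ::-1, ::-1]
        assert (flipped != template.mask).sum() < 0.01 * template.n_voxels

    def test_unreachable_count_reports_nearest(self):
        with pytest.raises(ValueError, match="nearest achievable"):
            build_template(search_bounds=(2.0, 2.2))

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_template(spacing=(0.0, 0.34, 0.34))


class TestStandardizeShape:
    def _uniform_cell(self):
        cfg = SimConfig(n_frames=1, poisson_scale=0, gaussian_sd=0,
                        accumulation_contrast=1.0)
        series, truth = make_cell_couple(cfg, PatternScript.uniform("none", 1))
        return series.data[0], truth

    def test_uniform_cell_gives_flat_vector(self, template):
        vol, truth = self._uniform_cell()
        sc = standardize_shape(vol, truth.cell_mask, template, SPACING)
        assert sc.vector.std() / sc.vector.mean() < 0.05

    def test_point_mass_lands_in_top_layer(self, template):
        _, truth = self._uniform_cell()
        vol = np.zeros_like(truth.cell_mask, dtype=float)
        ic = truth.interface_center_um
        iz = int(round(ic[0] / SPACING[0])) + 1
        vol[iz, int(round(ic[1] / SPACING[1])), int(round(ic[2] / SPACING[2]))] = 1.0
        sc = standardize_shape(vol, truth.cell_mask, template, SPACING)
        assert sc.vector[template.axial_layer == 0].sum() >= 0.9

    def test_normalization_contract_random_input(self, template):
        _, truth = self._uniform_cell()
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 1, truth.cell_mask.shape) * truth.cell_mask
        sc = standardize_shape(vol, truth.cell_mask, template, SPACING)
        assert sc.vector.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(sc.vector >= 0)

    def test_empty_mask_rejected(self, template):
        with pytest.raises(ValueError, match="empty"):
            standardize_shape(np.zeros((5, 5, 5)), np.zeros((5, 5, 5), bool),
                              template, SPACING)


class TestEnrichment:
    def test_region_cardinality_and_tie_break(self, template):
        uniform = StandardizedCell(np.full(6628, 1 / 6628))
        region = compute_enrichment_region([uniform])
        assert region.cardinality == 663
        # degenerate all-uniform average: the first 663 voxels in fixed order
        assert np.array_equal(region.indices, np.arange(663))

    def test_top_layer_mass_selects_top_region(self, template):
        v = np.full(6628, 1e-12)
        top = template.axial_layer == 0
        v[top] = 1.0
        v /= v.sum()
        region = compute_enrichment_region([StandardizedCell(v)])
        n_top = int(top.sum())
        assert np.all(top[region.indices[:min(663, n_top)]])

    def test_uniform_enrichment_is_one(self):
        uniform = StandardizedCell(np.full(6628, 1 / 6628))
        region = compute_enrichment_region([uniform])
        assert enrichment(uniform, region) == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_upper_bound(self):
        region = compute_enrichment_region([StandardizedCell(np.full(6628, 1 / 6628))])
        v = np.zeros(6628)
        v[region.indices] = 1 / 663
        assert enrichment(StandardizedCell(v), region) == pytest.approx(6628 / 663, abs=1e-6)

    def test_thirty_percent_mass_arithmetic(self):
        region = compute_enrichment_region([StandardizedCell(np.full(6628, 1 / 6628))])
        v = np.full(6628, 0.70 / (6628 - 663))
        v[region.indices] = 0.30 / 663
        expected = (0.30 / 663) / (1.0 / 6628)
        assert enrichment(StandardizedCell(v), region) == pytest.approx(expected, rel=1e-9)

    def test_probability_vector_validation(self):
        with pytest.raises(ValueError):
            StandardizedCell(np.full(6628, 1.0))
        with pytest.raises(ValueError):
            StandardizedCell(-np.full(6628, 1 / 6628))

    def test_mismatched_template_rejected(self):
        region = EnrichmentRegion(mask=np.zeros(10, bool), indices=np.array([], int))
        with pytest.raises(ValueError, match="different templates"):
            enrichment(StandardizedCell(np.full(6628, 1 / 6628)), region)


class TestRotationInvariance:
    def test_enrichment_invariant_under_prerotation(self, template):
        cfg = SimConfig(n_frames=1, poisson_scale=0, gaussian_sd=0,
                        accumulation_contrast=3.0)
        series, truth = make_cell_couple(cfg, PatternScript.uniform("central", 1))
        aligned = standardize_shape(series.data[0], truth.cell_mask, template, SPACING)
        region = compute_enrichment_region([aligned])
        e_aligned = enrichment(aligned, region)

        s2, t2 = make_cell_couple(cfg, PatternScript.uniform("central", 1),
                                  interface_normal=(0.0, -1.0, 0.0))
        ann = SynapseAnnotation(
            0, tuple(t2.interface_center_um),
            tuple(t2.interface_center_um + t2.axis_into_cell * 8.0))
        out = reorient_interface_up(s2.data[0], t2.cell_mask, ann, SPACING)
        rotated = standardize_shape(out.volume, out.mask, template, SPACING)
        e_rotated = enrichment(rotated, region)
        assert e_rotated == pytest.approx(e_aligned, rel=0.02)
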
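"""Tests of the synthetic-data generator's contracts and ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from synapsequant.membrane import arc_length
from synapsequant.synthgen import (LABELS, PatternGeometry, PatternScript, SimConfig,
                                   make_cell_couple, make_cohort, make_membrane_trace,
                                   make_sted_field)


class TestSimConfig:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            SimConfig(voxel_spacing=(0.0, 0.34, 0.34))

    def test_rejects_zero_frames(self):
        with pytest.raises(ValueError):
            SimConfig(n_frames=0)

    def test_rejects_interface_wider_than_cell(self):
        with pytest.raises(ValueError):
            SimConfig(interface_radius_um=6.0, t_cell_radius_um=5.0)


class TestMakeCellCouple:
    def test_no_contrast_means_no_signal(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, accumulation_contrast=1.0)
        series, truth = make_cell_couple(cfg, PatternScript.uniform("central", 1))
        assert truth.labels == ["none"]
        bg = cfg.background_intensity
        assert not np.any(series.data[0] > 1.4 * bg)

    def test_central_script_yields_one_central_region(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, accumulation_contrast=2.0)
        series, truth = make_cell_couple(cfg, PatternScript.uniform("central", 1))
        from scipy import ndimage
        above = series.data[0] > 1.4 * cfg.background_intensity
        labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), bool))
        assert n == 1
        centroid = np.asarray(ndimage.center_of_mass(above)) * np.asarray(series.spacing)
        inplane = centroid[1:] - truth.interface_center_um[1:]
        assert np.hypot(*inplane) < 0.5 * truth.interface_radius_um

    def test_seed_reproducibility_is_bitwise(self):
        cfg = SimConfig(n_frames=2, seed=42)
        s1, _ = make_cell_couple(cfg, PatternScript.uniform("central", 2))
        s2, _ = make_cell_couple(cfg, PatternScript.uniform("central", 2))
        assert np.array_equal(s1.data, s2.data)

    def test_different_seeds_differ(self):
        s1, _ = make_cell_couple(SimConfig(n_frames=1, seed=1),
                                 PatternScript.uniform("central", 1))
        s2, _ = make_cell_couple(SimConfig(n_frames=1, seed=2),
                                 PatternScript.uniform("central", 1))
        assert not np.array_equal(s1.data, s2.data)

    def test_script_longer_than_movie_rejected(self, quiet_config):
        with pytest.raises(ValueError, match="longer"):
            make_cell_couple(quiet_config, PatternScript.uniform("central", 5))

    def test_impossible_invagination_depth_rejected(self, quiet_config):
        geom = PatternGeometry(invagination_depth_um=20.0)
        with pytest.raises(ValueError, match="exceeds"):
            make_cell_couple(quiet_config,
                             PatternScript.uniform("invagination", 1, geometry=geom))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PatternScript(["cSMAC"])

    def test_shallow_invagination_rejected(self):
        with pytest.raises(ValueError, match="1 µm"):
            PatternScript(["invagination"],
                          geometry=PatternGeometry(invagination_depth_um=0.5))

    def test_accumulation_masks_lie_inside_cell(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, n_frames=2)
        _, truth = make_cell_couple(cfg, PatternScript(["diffuse", "peripheral"]))
        for acc in truth.accumulation_masks:
            assert not np.any(acc & ~truth.cell_mask)


class TestMakeCohort:
    def schedule(self):
        return pd.DataFrame({"central": [1.0, 0.5], "none": [0.0, 0.5]},
                            index=[0.0, 20.0])

    def test_degenerate_schedule_all_central(self):
        sched = pd.DataFrame({"central": [1.0]}, index=[0.0])
        ds = make_cohort(10, sched, SimConfig(n_frames=1, seed=3))
        assert all(t.labels == ["central"] for _, t in ds)

    def test_empty_cohort(self):
        assert make_cohort(0, self.schedule(), SimConfig(n_frames=2)) == []

    def test_invalid_probabilities_rejected(self):
        bad = pd.DataFrame({"central": [0.6], "none": [0.5]}, index=[0.0])
        with pytest.raises(ValueError, match="sum to 1"):
            make_cohort(1, bad, SimConfig(n_frames=1))
        neg = pd.DataFrame({"central": [-0.1], "none": [1.1]}, index=[0.0])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            make_cohort(1, neg, SimConfig(n_frames=1))

    def test_cohort_reproducible_from_seed(self):
        cfg = SimConfig(n_frames=2, seed=11)
        d1 = make_cohort(3, self.schedule(), cfg)
        d2 = make_cohort(3, self.schedule(), cfg)
        for (s1, t1), (s2, t2) in zip(d1, d2):
            assert np.array_equal(s1.data, s2.data)
            assert t1.labels == t2.labels

    def test_realized_frequencies_converge_to_schedule(self):
        # large-n multinomial convergence, checked against 3 binomial SEs
        p = 0.49
        sched = pd.DataFrame({"central": [p], "none": [1 - p]}, index=[0.0])
        n = 500
        ds = make_cohort(n, sched, SimConfig(n_frames=1, seed=17))
        labels = [t.labels[0] for _, t in ds]
        freq = np.mean([lab == "central" for lab in labels])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) <= 3 * se


class TestMakeStedField:
    def test_half_max_volume_matches_truth(self):
        img, _ = make_sted_field([0.23], config=SimConfig(seed=3), speckle_sd=0.0,
                                 amplitude_jitter=(1.0, 1.0))
        vol = float((img > img.max() / 2).sum()) * 0.05 ** 3
        assert vol == pytest.approx(0.23, rel=0.10)

    def test_empty_volume_list_is_pure_background(self):
        img, truth = make_sted_field([], config=SimConfig(seed=1), speckle_sd=0.0)
        assert np.all(img == 0)
        assert truth.puncta_labels.max() == 0

    def test_subvoxel_punctum_rejected(self):
        with pytest.raises(ValueError, match="smaller than one voxel"):
            make_sted_field([1e-5], config=SimConfig(seed=1))

    def test_too_close_centers_rejected(self):
        with pytest.raises(ValueError, match="0.1"):
            make_sted_field([0.1, 0.1], config=SimConfig(seed=1),
                            centers_um=[[1, 1, 1], [1, 1, 1.05]])

    def test_close_puncta_split_by_truth_seeded_watershed(self):
        # oracle: seeded region growing (watershed) from the true centroids
        from synapsequant.puncta import PunctaParams, segment_puncta
        centers = [[1.6, 1.6, 1.45], [1.6, 1.6, 2.15]]
        img, truth = make_sted_field([0.1, 0.1], config=SimConfig(seed=2),
                                     centers_um=centers, speckle_sd=2.0)
        pset = segment_puncta(img, PunctaParams(), markers_um=truth.punctum_centers_um)
        assert len(pset) == 2

    def test_deterministic_given_seed(self):
        a, _ = make_sted_field([0.2, 0.15], config=SimConfig(seed=9))
        b, _ = make_sted_field([0.2, 0.15], config=SimConfig(seed=9))
        assert np.array_equal(a, b)


class TestMakeMembraneTrace:
    def test_flat_membrane_arc_equals_span(self):
        trace, truth = make_membrane_trace(0.0, 1.0, 4.0, 100)
        assert truth.arc_length_um == 4.0
        assert arc_length(trace.points) == pytest.approx(4.0, abs=1e-12)

    def test_polyline_matches_quadrature_oracle(self):
        trace, truth = make_membrane_trace(0.5, 1.0, 4.0, 2000)
        assert arc_length(trace.points) == pytest.approx(truth.arc_length_um, rel=1e-3)

    def test_sampling_convergence(self):
        t_hi, truth = make_membrane_trace(0.5, 1.0, 4.0, 1000)
        t_lo, _ = make_membrane_trace(0.5, 1.0, 4.0, 500)
        hi, lo = arc_length(t_hi.points), arc_length(t_lo.points)
        assert abs(hi - lo) / truth.arc_length_um < 0.01

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_membrane_trace(0.5, 1.0, 0.0, 100)
        with pytest.raises(ValueError):
            make_membrane_trace(0.5, 1.0, 4.0, 1)
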
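"""Synthetic generator: geometry, forward model, planted ground truth."""

import numpy as np
import pytest

from ictolat import (
    GroundTruth,
    SourceSpaceSpec,
    generate_ictal_sources,
    generate_leadfield,
    generate_planted_network,
    project_to_scalp,
)
from ictolat.montage import CHANNELS_1020, electrode_positions
from ictolat.network import instantaneous_phase, plv_matrix
from ictolat.rois import HEMISPHERE_OF_ROI, N_ROIS, ROI_LABELS


def roi_level_plv(spec, src):
    """ROI-mean signals -> Hilbert phases -> PLV matrix (test oracle)."""
    rows = [
        src[np.flatnonzero(spec.roi_of_source == r)].mean(axis=0)
        for r in ROI_LABELS
    ]
    return plv_matrix(instantaneous_phase(np.vstack(rows)))


class TestSourceSpace:
    def test_every_roi_nonempty_and_positions_on_unit_sphere(self):
        spec = SourceSpaceSpec(n_sources=60, seed=3)
        assert set(spec.roi_of_source) == set(ROI_LABELS)
        radii = np.linalg.norm(spec.positions, axis=1)
        assert np.all(np.abs(radii - 1.0) < 1e-9)
        assert spec.positions.shape == (60, 3)

    def test_too_few_sources_rejected(self):
        with pytest.raises(ValueError, match="too few sources"):
            SourceSpaceSpec(n_sources=14)

    def test_deterministic_given_seed(self):
        a, b = SourceSpaceSpec(300, seed=5), SourceSpaceSpec(300, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.roi_of_source, b.roi_of_source)


class TestLeadfield:
    def test_shape_and_determinism(self):
        spec = SourceSpaceSpec(n_sources=300, seed=1)
        lf1 = generate_leadfield(spec, 19)
        lf2 = generate_leadfield(SourceSpaceSpec(n_sources=300, seed=1), 19)
        assert lf1.gain.shape == (19, 300)
        assert np.array_equal(lf1.gain, lf2.gain)

    def test_north_pole_source_peaks_at_vertex_channel(self):
        """Independent oracle: evaluate the dipole potential at every
        electrode for a radial source at the north pole and take argmax."""
        spec = SourceSpaceSpec(n_sources=15, seed=0)
        spec.positions[0] = [0.0, 0.0, 1.0]  # move pinned source to the pole
        lf = generate_leadfield(spec)
        elec = electrode_positions()
        diff = elec - np.array([0.0, 0.0, 1.0])
        oracle = (diff @ np.array([0.0, 0.0, 1.0])) / (
            4 * np.pi * np.linalg.norm(diff, axis=1) ** 3
        )
        assert np.argmax(np.abs(lf.gain[:, 0])) == np.argmax(np.abs(oracle))
        assert CHANNELS_1020[np.argmax(np.abs(lf.gain[:, 0]))] == "Cz"

    def test_forward_model_is_linear_in_dipole_moment(self, small_leadfield):
        # doubling a source's activity doubles its scalp footprint
        src = np.zeros((small_leadfield.n_sources, 10))
        src[7] = np.arange(10.0)
        rec1 = project_to_scalp(src, small_leadfield, 0.0, seed=0)
        rec2 = project_to_scalp(2 * src, small_leadfield, 0.0, seed=0)
        assert np.allclose(rec2.data, 2 * rec1.data)


class TestIctalSources:
    def test_sample_count_16s_at_256hz(self, small_spec, truth):
        src = generate_ictal_sources(small_spec, truth, 256.0, 16.0, seed=0)
        assert src.shape == (small_spec.n_sources, 4096)

    def test_short_seizure_rejected(self, small_spec, truth):
        with pytest.raises(ValueError, match="too short"):
            generate_ictal_sources(small_spec, truth, 256.0, 15.9, seed=0)

    def test_invalid_rate_rejected(self, small_spec, truth):
        with pytest.raises(ValueError, match="sampling rate"):
            generate_ictal_sources(small_spec, truth, 200.0, 16.0, seed=0)

    def test_bit_reproducible(self, small_spec, truth):
        a = generate_ictal_sources(small_spec, truth, 256.0, 16.0, seed=9)
        b = generate_ictal_sources(small_spec, truth, 256.0, 16.0, seed=9)
        assert np.array_equal(a, b)

    def test_planted_focus_dominates_roi_plv(self, small_spec, truth):
        """Monte-Carlo ground-truth recoverability: the planted focus has
        the largest ROI-level PLV row-sum in >= 90% of seeds."""
        f = truth.focus_index
        hits = 0
        for seed in range(20):
            src = generate_ictal_sources(small_spec, truth, 256.0, 16.0, seed)
            plv = roi_level_plv(small_spec, src)
            hits += int(np.argmax(plv.sum(axis=1)) == f)
        assert hits >= 18

    def test_no_focus_no_dominant_row(self, small_spec):
        """Without a planted focus no ROI systematically dominates."""
        f = ROI_LABELS.index("Superior temporal right")
        hits = sum(
            int(
                np.argmax(
                    roi_level_plv(
                        small_spec,
                        generate_ictal_sources(small_spec, None, 256.0, 16.0, s),
                    ).sum(axis=1)
                )
                == f
            )
            for s in range(20)
        )
        # uniform rank would give ~20/15 ~= 1.3 hits; allow generous slack
        assert hits <= 6


class TestProjectToScalp:
    def test_single_source_projection_is_gain_times_signal(self, small_leadfield):
        sig = np.sin(np.linspace(0, 6, 100))
        src = np.zeros((small_leadfield.n_sources, 100))
        src[11] = sig
        rec = project_to_scalp(src, small_leadfield, 0.0, seed=0)
        assert np.allclose(rec.data, np.outer(small_leadfield.gain[:, 11], sig))

    def test_additive_noise_sd(self, small_leadfield):
        src = np.zeros((small_leadfield.n_sources, 20000))
        clean = project_to_scalp(src, small_leadfield, 0.0, seed=1)
        noisy = project_to_scalp(src, small_leadfield, 1.0, seed=1)
        sds = (noisy.data - clean.data).std(axis=1)
        assert np.all(np.abs(sds - 1.0) < 0.05)

    def test_same_seed_identical(self, small_leadfield):
        src = np.random.default_rng(0).standard_normal((small_leadfield.n_sources, 50))
        a = project_to_scalp(src, small_leadfield, 0.5, seed=7)
        b = project_to_scalp(src, small_leadfield, 0.5, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_shape_mismatch_rejected(self, small_leadfield):
        with pytest.raises(ValueError, match="sources"):
            project_to_scalp(np.zeros((3, 10)), small_leadfield, 0.0, seed=0)


class TestPlantedNetwork:
    def test_invariants(self):
        net = generate_planted_network(15, focus=3, strength=10.0, seed=2)
        a = net.adjacency
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)
        assert np.all((a >= 0) & (a <= 1))

    def test_focus_has_max_weighted_degree(self):
        net = generate_planted_network(15, focus=3, strength=10.0, seed=4)
        assert np.argmax(net.adjacency.sum(axis=1)) == 3

    def test_strength_one_is_exchangeable_baseline(self):
        # with strength=1 the focus is not distinguished: it tops the
        # weighted degree about as often as any other node (p ~ 1/15)
        hits = sum(
            np.argmax(
                generate_planted_network(15, 3, 1.0, seed=s).adjacency.sum(axis=1)
            )
            == 3
            for s in range(30)
        )
        assert hits <= 8

    def test_ground_truth_validation(self):
        with pytest.raises(ValueError, match="midline"):
            GroundTruth(focus_roi="Precuneus")
        with pytest.raises(ValueError, match="coupling_gain"):
            GroundTruth(focus_roi="Insula left", coupling_gain=1.0)
        assert GroundTruth(focus_roi="Insula left").focus_hemisphere == "left"

    def test_hemisphere_table_consistency(self):
        assert sum(h == "midline" for h in HEMISPHERE_OF_ROI.values()) == 5
        assert len(ROI_LABELS) == N_ROIS == 15
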
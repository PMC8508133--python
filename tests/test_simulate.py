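"""Synthetic-data generator: dwell/bleach/censoring process and rendering."""

import math

import numpy as np
import pytest

from smres import (
    BoundState,
    Condition,
    GroundTruth,
    ImagingScheme,
    render_movie,
    simulate_tracks,
)
from smres.simulate import simulate_track_tables, tracks_to_table


def single_state_truth(k=0.0, bleach=0.0, **kw) -> GroundTruth:
    return GroundTruth(bound_states=(BoundState(k, 1.0),), bleach_rate=bleach,
                       bound_fraction=1.0, **kw)


class TestSimulateTracks:
    def test_no_decay_processes_tracks_span_to_movie_end(self, small_scheme):
        """With k = 0 and no bleaching every track survives to the last frame."""
        truth = single_state_truth()
        tracks, meta = simulate_tracks(truth, small_scheme, 0, 50, seed=3)
        n_frames = small_scheme.conditions[0].n_frames
        assert meta["n_movie_end"] == 50
        for t in tracks:
            assert t.end_cause == "movie_end"
            assert t.frames[-1] == n_frames - 1

    def test_mean_observed_duration_matches_closed_form(self):
        """Mean duration of the discrete observation process equals
        tau * e^{-q} / (1 - e^{-q}) with q = k*tau + a; here a = 0 and the
        movie is long enough that window censoring is negligible."""
        k, tau = 0.01, 1.6
        scheme = ImagingScheme(conditions=(Condition(tau, 50_000.0),))
        truth = single_state_truth(k=k)
        tracks, _ = simulate_tracks(truth, scheme, 0, 10_000, seed=11)
        durations = np.array([(t.span_frames - 1) * tau for t in tracks])
        q = k * tau
        mean_theory = tau * math.exp(-q) / (1 - math.exp(-q))
        sem = durations.std(ddof=1) / math.sqrt(len(durations))
        assert abs(durations.mean() - mean_theory) < 3 * sem
        # and the closed form itself is within half a percent of 1/k_eff
        assert mean_theory == pytest.approx(1 / k, rel=0.02)

    def test_five_condition_scheme_yields_five_track_tables(self):
        """One track table per frame cycle time of the five-condition run."""
        scheme = ImagingScheme.from_pairs(
            [(0.1, 30.0), (0.4, 120.0), (1.6, 480.0), (6.4, 960.0), (14.0, 1400.0)]
        )
        truth = single_state_truth(k=0.01, bleach=1.0)
        tables = simulate_track_tables(truth, scheme, 50, seed=5)
        assert sorted(tables) == [0.1, 0.4, 1.6, 6.4, 14.0]
        for tab in tables.values():
            assert set(tab.columns) == {"molecule_id", "frame", "x", "y", "condition"}

    def test_bleached_fraction_monotone_in_bleach_rate(self, small_scheme):
        fractions = []
        for kb in (0.5, 2.0, 8.0):
            truth = single_state_truth(k=0.005, bleach=kb)
            _, meta = simulate_tracks(truth, small_scheme, 1, 4000, seed=7)
            fractions.append(meta["n_bleached"] / meta["n_bound"])
        assert fractions[0] < fractions[1] < fractions[2]

    def test_time_lapse_principle_duration_grows_with_cycle_time(self):
        """At fixed per-frame bleaching, observed durations in seconds grow
        with the cycle time because the bleaching cost per unit time falls."""
        scheme = ImagingScheme.from_pairs(
            [(0.1, 3000.0), (1.0, 30_000.0), (8.0, 240_000.0)]
        )
        truth = single_state_truth(k=0.01, bleach=1.0)  # a = 0.05/frame
        means = []
        for ci, cond in enumerate(scheme.conditions):
            tracks, _ = simulate_tracks(truth, scheme, ci, 3000, seed=13)
            means.append(np.mean([(t.span_frames - 1) * cond.cycle_time
                                  for t in tracks]))
        assert means[0] < means[1] < means[2]

    def test_empirical_survival_within_dkw_band(self):
        """Single-state observed durations follow
        S(n tau) = exp(-k n tau) exp(-k_b t_int n) within DKW bounds."""
        k, kb, tau = 0.05, 0.4, 1.0
        scheme = ImagingScheme(conditions=(Condition(tau, 30_000.0),))
        truth = single_state_truth(k=k, bleach=kb)
        n_mol = 10_000
        tracks, _ = simulate_tracks(truth, scheme, 0, n_mol, seed=17)
        spans = np.array([t.span_frames for t in tracks])
        a = kb * scheme.integration_time
        n = np.arange(0, 200)
        s_theory = np.exp(-(k * tau + a) * n)
        s_emp = np.array([(spans >= i + 1).mean() for i in n])
        eps = math.sqrt(math.log(2 / 1e-6) / (2 * n_mol))
        assert np.max(np.abs(s_emp - s_theory)) < eps

    def test_identical_seeds_give_byte_identical_tables(self, small_scheme):
        truth = single_state_truth(k=0.02, bleach=1.0)
        out = []
        for _ in range(2):
            tracks, _ = simulate_tracks(truth, small_scheme, 0, 300, seed=23)
            out.append(tracks_to_table(tracks, 0.1).to_csv(index=False))
        assert out[0] == out[1]

    def test_invalid_inputs_rejected(self, small_scheme):
        truth = single_state_truth(k=0.1)
        with pytest.raises(ValueError, match="n_molecules"):
            simulate_tracks(truth, small_scheme, 0, 0)
        with pytest.raises(ValueError, match="condition_index"):
            simulate_tracks(truth, small_scheme, 9, 10)
        with pytest.raises(ValueError, match="field_size"):
            simulate_tracks(truth, small_scheme, 0, 10, field_size=(0, 10))
        with pytest.raises(ValueError, match="negative"):
            GroundTruth(bound_states=(BoundState(-1.0, 1.0),))
        with pytest.raises(ValueError, match="at least one"):
            GroundTruth(bound_states=())


class TestGroundTruth:
    def test_state_weights_follow_dwell_weighting(self):
        truth = GroundTruth(
            bound_states=(BoundState(0.1, 0.5), BoundState(1.0, 0.5))
        )
        np.testing.assert_allclose(truth.state_weights, [10 / 11, 1 / 11])
        assert truth.slowest_binding_time() == pytest.approx(10.0)

    def test_default_labeling_density_matches_experiment(self):
        truth = GroundTruth(bound_states=(BoundState(0.1, 1.0),))
        assert truth.labeling_density == 6.0

    def test_json_round_trip(self, tmp_path):
        truth = GroundTruth(
            bound_states=(BoundState(1 / 910, 0.3), BoundState(0.5, 0.7)),
            bleach_rate=1.0,
        )
        path = tmp_path / "truth.json"
        truth.to_json(path)
        assert GroundTruth.from_json(path) == truth


class TestRenderMovie:
    def test_no_tracks_no_noise_gives_flat_background(self, small_scheme):
        movie = render_movie([], small_scheme, 0, field_size=(32, 32),
                             background_level=10.0, noise_model="none")
        assert movie.shape[0] == small_scheme.conditions[0].n_frames
        assert np.all(movie == 10.0)

    def test_intensity_maximum_lies_at_molecule_position(self, small_scheme):
        """Brute-force pixel scan: the global argmax of each rendered frame
        is within one pixel of the molecule's true position."""
        from smres.simulate import TruthTrack

        n_frames = small_scheme.conditions[0].n_frames
        track = TruthTrack(
            molecule_id=0, state_index=0, appearance_time=0.0, true_dwell=1e9,
            frames=np.arange(n_frames),
            x=np.full(n_frames, 21.3), y=np.full(n_frames, 10.6),
            end_cause="movie_end",
        )
        movie = render_movie([track], small_scheme, 0, field_size=(32, 48),
                             amplitude=50.0, background_level=10.0,
                             noise_model="none")
        for frame in movie:
            iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
            assert abs(ix - 21.3) <= 1.0 and abs(iy - 10.6) <= 1.0

    def test_rendered_spot_density_can_match_labeling_density(self):
        """Molecule count calibrated so the mean number of rendered spots per
        frame is close to the experimental labeling density of 6."""
        tau, movie_len = 0.4, 120.0
        scheme = ImagingScheme(conditions=(Condition(tau, movie_len),))
        truth = single_state_truth(k=0.05, bleach=1.0)
        n_frames = int(movie_len / tau)
        # expected visible frames per molecule, from the exact span law
        m = np.arange(1, n_frames + 1)
        p_span = (np.exp(-0.05 * tau * (m - 1))
                  * np.exp(-1.0 * scheme.integration_time) ** (m - 1)
                  * (n_frames - m + 1) / n_frames)
        e_span = p_span.sum()
        n_mol = int(round(truth.labeling_density * n_frames / e_span))
        tracks, _ = simulate_tracks(truth, scheme, 0, n_mol, seed=29)
        visible = np.zeros(n_frames)
        for t in tracks:
            visible[t.frames] += 1
        assert visible.mean() == pytest.approx(6.0, rel=0.1)

    def test_invalid_render_parameters_rejected(self, small_scheme):
        with pytest.raises(ValueError, match="psf_sigma"):
            render_movie([], small_scheme, 0, psf_sigma=0.0)
        with pytest.raises(ValueError, match="background"):
            render_movie([], small_scheme, 0, background_level=0.0)
        with pytest.raises(ValueError, match="noise model"):
            render_movie([], small_scheme, 0, noise_model="speckle")
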
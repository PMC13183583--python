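"""Synthetic-data generators: determinism, conservation laws, ground truth."""

import numpy as np
import pytest
from scipy import stats

from nucleoflux.kinetics import TransportParams
from nucleoflux.simulate import (
    CellSimSpec,
    FrameGeometry,
    RampSimSpec,
    TFSimSpec,
    bell_mode_force,
    bell_rupture_forces,
    bell_survival,
    gen_cell_timecourse,
    gen_frames,
    gen_ramp_trajectory,
    gen_tf_dataset,
)
from nucleoflux.tweezers import fjc_extension
from nucleoflux.tfsurvey import disorder_means, terminal_region


class TestCellTimecourse:
    def test_recovery_plateau_equals_accumulation(self, mcherry_params):
        spec = CellSimSpec(
            params=mcherry_params,
            activation_duration=0.0,
            recovery_duration=5e6,
            frame_interval=1e5,
            noise_cv=0.0,
            seed=0,
        )
        tc, _ = gen_cell_timecourse(spec)
        assert tc.ratio[-1] == pytest.approx(mcherry_params.K_e, abs=1e-9)

    def test_emptied_nucleus_starts_at_zero_ratio(self, recovery_only_spec):
        tc, _ = gen_cell_timecourse(recovery_only_spec)
        assert tc.ratio[0] == 0.0

    def test_ratio_at_200s_matches_closed_form(self, mcherry_params):
        spec = CellSimSpec(
            params=mcherry_params,
            activation_duration=0.0,
            recovery_duration=300.0,
            frame_interval=200.0,
            noise_cv=0.0,
            seed=0,
        )
        tc, _ = gen_cell_timecourse(spec)
        # second recovery frame sits at t = 200 s
        assert tc.ratio[1] == pytest.approx(0.692, abs=5e-4)

    def test_mass_conservation_every_frame(self, mcherry_params):
        spec = CellSimSpec(params=mcherry_params, noise_cv=0.0, seed=0)
        tc, truth = gen_cell_timecourse(spec)
        v = mcherry_params.v
        mass = v * truth["N_true"] + truth["C_true"]
        np.testing.assert_allclose(mass, mass[0], atol=1e-9)

    def test_seed_determinism(self, mcherry_params):
        spec = CellSimSpec(params=mcherry_params, noise_cv=0.15, seed=7)
        a, _ = gen_cell_timecourse(spec)
        b, _ = gen_cell_timecourse(spec)
        assert np.array_equal(a.ratio, b.ratio)
        c, _ = gen_cell_timecourse(
            CellSimSpec(params=mcherry_params, noise_cv=0.15, seed=8)
        )
        assert not np.array_equal(a.ratio, c.ratio)

    def test_invalid_spec_rejected(self, mcherry_params):
        with pytest.raises(ValueError):
            CellSimSpec(params=mcherry_params, frame_interval=0.0)
        with pytest.raises(ValueError):
            CellSimSpec(params=mcherry_params, noise_cv=-0.1)

    def test_activation_phase_empties_nucleus(self, mcherry_params):
        spec = CellSimSpec(params=mcherry_params, noise_cv=0.0, seed=0)
        tc, truth = gen_cell_timecourse(spec)
        act = tc.phase == "activation"
        assert np.all(np.diff(tc.ratio[act]) < 0)  # nucleus drains under light
        assert truth["N0_recovery"] < 0.1 * mcherry_params.Ne


class TestFrames:
    def test_constructed_nuclear_fraction(self, mcherry_params):
        # pick the frame where the kinetic truth puts ~30% of signal in the
        # nucleus and check the mask-summed fraction reproduces it exactly
        spec = CellSimSpec(
            params=mcherry_params, activation_duration=0.0, noise_cv=0.0, seed=0
        )
        stack, masks, truth = gen_frames(spec, FrameGeometry(background=0.0, gain=0.0))
        i = int(np.argmin(np.abs(truth["n_frac"] - 0.30)))
        nuc = stack.frames[i][masks.nucleus].sum()
        cell = stack.frames[i][masks.cell].sum()
        assert nuc / cell == pytest.approx(truth["n_frac"][i], abs=1e-6)

    def test_geometry_overlap_rejected(self):
        geom = FrameGeometry(cell=(48, 48, 20, 20), nucleus=(48, 48, 20, 20))
        with pytest.raises(ValueError):
            geom.masks()

    def test_seed_determinism_with_noise(self, mcherry_params):
        spec = CellSimSpec(params=mcherry_params, noise_cv=0.0, seed=11,
                           recovery_duration=300.0)
        g = FrameGeometry(gain=100.0)
        a = gen_frames(spec, g)[0].frames
        b = gen_frames(spec, g)[0].frames
        assert np.array_equal(a, b)


class TestRampTrajectory:
    def test_bell_mode_matches_analytic(self):
        rng = np.random.default_rng(123)
        f = bell_rupture_forces(1e-4, 0.25, 1.0, 10_000, rng)
        hist, edges = np.histogram(f, bins=np.arange(0, 200, 4.0))
        empirical_mode = edges[np.argmax(hist)] + 2.0
        assert empirical_mode == pytest.approx(bell_mode_force(1e-4, 0.25, 1.0), abs=4.0)

    def test_bell_distribution_matches_survival(self):
        rng = np.random.default_rng(7)
        f = bell_rupture_forces(1e-4, 0.25, 1.0, 10_000, rng)
        res = stats.kstest(f, lambda x: 1.0 - bell_survival(x, 1e-4, 0.25, 1.0))
        assert res.pvalue > 0.01

    def test_noiseless_step_size_matches_fjc(self):
        # one state with dLc = 65 nm forced to rupture near 50 pN
        spec = RampSimSpec(
            states=((2.8e-4, 0.5, 65.0),), noise_sd=0.0, seed=1, f_max=120.0
        )
        traj, events = gen_ramp_trajectory(spec)
        assert len(events) == 1
        e = events[0]
        jump = fjc_extension(e.F_U, 65.0)
        k = np.searchsorted(traj.time, e.t_U)
        assert traj.extension[k] - traj.extension[k - 1] == pytest.approx(jump, abs=0.2)
        # at exactly 50 pN the FJC jump is ~60.1 nm
        assert fjc_extension(50.0, 65.0) == pytest.approx(60.1, abs=0.1)

    def test_zero_states_smooth_monotone_baseline(self):
        spec = RampSimSpec(states=(), noise_sd=0.0, drift=0.3, seed=0)
        traj, events = gen_ramp_trajectory(spec)
        assert events == []
        assert np.all(np.diff(traj.extension) >= 0)

    def test_seed_determinism(self):
        spec = RampSimSpec(states=((6.3e-3, 1.0, 22.0),), seed=5)
        a, ea = gen_ramp_trajectory(spec)
        b, eb = gen_ramp_trajectory(spec)
        assert np.array_equal(a.extension, b.extension)
        assert [e.F_U for e in ea] == [e.F_U for e in eb]

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            RampSimSpec(states=((0.0, 1.0, 22.0),))


class TestTFDataset:
    def test_seed_determinism(self):
        spec = TFSimSpec(n_proteins=10, seed=3)
        a, _ = gen_tf_dataset(spec)
        b, _ = gen_tf_dataset(spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.disorder, rb.disorder)
            assert ra.nls == rb.nls

    def test_noiseless_region_elevation_closed_form(self):
        spec = TFSimSpec(
            n_proteins=1,
            length_range=(100, 100),
            baseline_disorder_mean=0.4,
            region_disorder_delta=0.2,
            noise_sd=0.0,
            seed=9,
        )
        recs, truth = gen_tf_dataset(spec)
        rec = recs[0]
        full, region = disorder_means(rec)
        lo, hi = truth[rec.id]["region"]
        frac = (hi - lo + 1) / rec.length
        assert region == pytest.approx(0.6, abs=1e-12)
        assert region - full == pytest.approx(0.2 * (1 - frac), abs=1e-12)

    def test_region_matches_terminal_rule(self):
        recs, truth = gen_tf_dataset(TFSimSpec(n_proteins=20, seed=4))
        for rec in recs:
            side, span = terminal_region(rec)
            assert truth[rec.id]["side"] == side
            assert truth[rec.id]["region"] == span

    def test_scores_clipped_to_unit_interval(self):
        recs, _ = gen_tf_dataset(TFSimSpec(n_proteins=5, noise_sd=0.6, seed=2))
        for rec in recs:
            assert rec.disorder.min() >= 0.0
            assert rec.disorder.max() <= 1.0
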
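"""Inverse problem: exact noiseless recovery, minimum-data rules,
uncertainty calibration, Monte-Carlo recovery and ROI tile fits."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from issdiff import (
    DiffusionParameters,
    FitOptions,
    InsufficientDataError,
    InstantaneousSource,
    NoiseModel,
    SpacetimeSampleSet,
    concentration_instantaneous,
    default_truth,
    fit,
    fit_roi_tiles,
    recovery_experiment,
    subtract_series,
    signal_to_concentration,
    summarize_recovery,
)
from issdiff.estimation import run_pipeline
from issdiff.phantom import generate_phantom

TRUTH = DiffusionParameters(d_x=1.0e-4, d_y=1.5e-4, d_z=0.8e-4,
                            k=1.4e-5, alpha=0.2)
MASS = 20.0
AMPLITUDE = MASS / TRUTH.alpha


def make_samples(n=60, seed=0, noise_sd=0.0):
    """Spacetime samples drawn from the closed form around a centred bolus."""
    rng = np.random.default_rng(seed)
    times = np.array([600.0, 1800.0, 3600.0, 7200.0, 14400.0, 21600.0])
    rows = []
    per = n // len(times)
    for t in times:
        sigma = np.sqrt(2 * TRUTH.diffusivities * t)
        xyz = rng.uniform(-1.5, 1.5, size=(per, 3)) * sigma
        rows.append(np.column_stack([xyz, np.full(per, t)]))
    pts = np.vstack(rows)[:n]
    c = concentration_instantaneous(TRUTH, InstantaneousSource(mass=MASS), pts)
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=c.shape)
    df = pd.DataFrame(np.column_stack([pts, np.clip(c, 0, None)]),
                      columns=["x_mm", "y_mm", "z_mm", "t_s", "conc_mM"])
    return SpacetimeSampleSet(data=df)


def rel(a, b):
    return abs(a - b) / abs(b)


class TestNoiselessFit:
    def test_exact_recovery(self):
        """60 noiseless samples recover every parameter to 1e-6 relative."""
        r = fit(make_samples(60))
        assert rel(r.d_x, TRUTH.d_x) < 1e-6
        assert rel(r.d_y, TRUTH.d_y) < 1e-6
        assert rel(r.d_z, TRUTH.d_z) < 1e-6
        assert rel(r.k, TRUTH.k) < 1e-6
        assert rel(r.amplitude, AMPLITUDE) < 1e-6
        assert r.converged

    def test_stderrs_vanish_without_noise(self):
        r = fit(make_samples(60))
        assert r.stderr["d_x"] < 1e-8 * r.d_x
        assert r.stderr["k"] < 1e-8 * max(r.k, 1e-12)

    def test_order_invariance(self):
        s = make_samples(60)
        perm = s.data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        r1 = fit(s, FitOptions(seed=3))
        r2 = fit(SpacetimeSampleSet(data=perm), FitOptions(seed=3))
        for attr in ("d_x", "d_y", "d_z", "k", "amplitude"):
            assert rel(getattr(r1, attr), getattr(r2, attr)) < 1e-6

    def test_fixed_mass_alpha_recovers_volume_fraction(self):
        opts = FitOptions(amplitude_handling="fixed_mass_alpha", mass=MASS)
        r = fit(make_samples(60), opts)
        assert rel(r.alpha, TRUTH.alpha) < 1e-6


class TestMinimumData:
    def test_five_samples_rejected(self):
        s = make_samples(60)
        five = SpacetimeSampleSet(data=s.data.iloc[:5].reset_index(drop=True))
        with pytest.raises(InsufficientDataError):
            fit(five)

    def test_six_samples_spanning_times_and_positions_accepted(self):
        pts = np.array([
            [0.5, 0.0, 0.0, 600.0], [0.0, 0.5, 0.0, 600.0],
            [0.0, 0.0, 0.5, 600.0], [1.0, 0.0, 0.0, 3600.0],
            [0.0, 1.0, 0.0, 3600.0], [0.0, 0.0, 1.0, 3600.0]])
        c = concentration_instantaneous(TRUTH, InstantaneousSource(mass=MASS), pts)
        df = pd.DataFrame(np.column_stack([pts, c]),
                          columns=["x_mm", "y_mm", "z_mm", "t_s", "conc_mM"])
        r = fit(SpacetimeSampleSet(data=df))
        assert r.n_samples == 6

    def test_single_time_rejected(self):
        s = make_samples(60)
        one_t = s.data[s.data["t_s"] == 600.0].reset_index(drop=True)
        with pytest.raises(InsufficientDataError):
            fit(SpacetimeSampleSet(data=one_t))


class TestUncertainty:
    def test_doubling_noise_doubles_stderr(self):
        """Linear-Gaussian scaling: SE is proportional to the noise SD
        (checked over 25 paired replicates)."""
        ratios = []
        for rep in range(25):
            r1 = fit(make_samples(60, seed=100 + rep, noise_sd=0.01),
                     FitOptions(multistart=2, seed=rep))
            r2 = fit(make_samples(60, seed=100 + rep, noise_sd=0.02),
                     FitOptions(multistart=2, seed=rep))
            if r1.stderr["d_x"] > 0:
                ratios.append(r2.stderr["d_x"] / r1.stderr["d_x"])
        assert np.median(ratios) == pytest.approx(2.0, rel=0.25)

    def test_average_d_stderr_matches_monte_carlo(self):
        """Delta-method SE of the average D agrees with the empirical SD
        over 100 simulated fits within 30%."""
        noise_sd = 0.05
        fits = [fit(make_samples(60, seed=200 + i, noise_sd=noise_sd),
                    FitOptions(multistart=1, seed=i)) for i in range(100)]
        avg_ds = np.array([f.average_d for f in fits])
        reported = np.median([f.stderr["average_d"] for f in fits])
        empirical = avg_ds.std(ddof=1)
        assert reported == pytest.approx(empirical, rel=0.30)


class TestRecoveryHarness:
    def test_noiseless_recovery_is_exact(self, noiseless_truth):
        table = recovery_experiment(noiseless_truth, n_reps=2, seed=0)
        summary = summarize_recovery(table)
        assert (summary["rmse_rel"] < 1e-6).all()
        assert (summary["bias_rel"].abs() < 1e-6).all()

    def test_requires_two_reps(self, noiseless_truth):
        with pytest.raises(Exception):
            recovery_experiment(noiseless_truth, n_reps=1, seed=0)

    def test_anisotropy_ordering_preserved_under_noise(self):
        """Median estimates keep Dy > Dx > Dz under the default anisotropic
        truth with 5% Rician noise (small replicate count here; the full
        study lives in the acceptance suite)."""
        truth = default_truth(seed=0)
        table = recovery_experiment(truth, n_reps=5, seed=11)
        ok = table[table["ok"]]
        med = {p: ok[f"{p}_hat"].median() for p in ("d_x", "d_y", "d_z")}
        assert med["d_y"] > med["d_x"] > med["d_z"]


class TestRoiTiles:
    def test_homogeneous_noiseless_tiles_agree(self, noiseless_truth):
        series, truth = generate_phantom(noiseless_truth)
        dsi = subtract_series(series)
        conc = [signal_to_concentration(d, truth.calibration)[0] for d in dsi]
        results = fit_roi_tiles(conc, series.times, series.affine,
                                truth.source.position, tiling=(2, 2),
                                threshold=1e-6)
        assert len(results) == 4
        dxs = [r.d_x for r in results.values()]
        assert max(dxs) - min(dxs) < 1e-6 * TRUTH.d_x
        for r in results.values():
            assert rel(r.d_x, TRUTH.d_x) < 1e-5

    def test_empty_tile_skipped_others_unaffected(self, noiseless_truth):
        series, truth = generate_phantom(noiseless_truth)
        dsi = subtract_series(series)
        conc = [signal_to_concentration(d, truth.calibration)[0] for d in dsi]
        # wipe one quadrant entirely so its tile has no samples
        for f in conc:
            f[:21, :21, :] = 0.0
        with pytest.warns(UserWarning, match="skipped"):
            results = fit_roi_tiles(conc, series.times, series.affine,
                                    truth.source.position, tiling=(2, 2),
                                    threshold=1e-6)
        assert len(results) == 3


class TestBounds:
    def test_estimates_within_bounds_or_flagged(self):
        r = fit(make_samples(60, seed=9, noise_sd=0.5), FitOptions(seed=9))
        assert 1e-7 <= r.d_x <= 1e-1
        assert 0.0 <= r.k <= 1e-2
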
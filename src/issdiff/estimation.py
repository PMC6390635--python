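"""Nonlinear least-squares estimation of diffusion and clearance parameters.

Given spacetime concentration samples (x, y, z, t, C) around a point source,
estimates the diagonal diffusion tensor (Dx, Dy, Dz), the clearance rate k
and the source amplitude by fitting the closed-form solution with a bounded
trust-region optimiser and seeded multistart.

Identifiability: the bolus solution depends on tracer mass M and ISS volume
fraction alpha only through the ratio M/alpha, so a single fit cannot
separate them.  The fitter therefore estimates a lumped amplitude
A = M/alpha; when M is known (``amplitude_handling="fixed_mass_alpha"``)
alpha is reported as M/A.

Positive parameters (Dx, Dy, Dz, A) are optimised in log-space for
stability; k stays linear with a k >= 0 bound.  Standard errors come from
the Jacobian at the optimum (sigma^2 (J'J)^-1) with delta-method
propagation back to the natural scale and onward to the average diffusion
coefficient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidInputError, NumericalError
from .imaging import (
    Calibration,
    ImageSeries,
    MIN_SAMPLES,
    SpacetimeSampleSet,
    estimate_background_sd,
    extract_samples,
    signal_to_concentration,
    subtract_series,
)
from .model import (
    DiffusionParameters,
    average_diffusion,
    half_life,
    point_source_kernel,
)

__all__ = ["FitOptions", "FitResult", "fit", "recovery_experiment",
           "summarize_recovery", "fit_roi_tiles"]

# optimisation bounds on the natural scale
_D_BOUNDS = (1e-7, 1e-1)     # mm^2/s
_K_BOUNDS = (0.0, 1e-2)      # 1/s
_A_BOUNDS = (1e-6, 1e9)      # nmol (lumped M/alpha)


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit`.

    ``model``: "instantaneous" (bolus, the default) — the closed form used
    by the protocol.  ``amplitude_handling``: "fit_amplitude" reports the
    lumped A = M/alpha; "fixed_mass_alpha" additionally reports
    alpha = mass/A and requires ``mass``.  ``multistart`` perturbed restarts
    (x/÷3, seeded) around the auto initial guess.
    """

    model: str = "instantaneous"
    amplitude_handling: str = "fit_amplitude"
    mass: float | None = None
    initial: dict | str = "auto"
    multistart: int = 8
    loss: str = "least_squares"
    max_iterations: int = 400
    tolerance: float = 1e-14
    seed: int = 0
    average_convention: str = "rss"
    d_free: float | None = None  # free-solution D for tortuosity, mm^2/s

    def __post_init__(self):
        if self.model not in ("instantaneous",):
            raise InvalidInputError(f"unsupported fit model {self.model!r}")
        if self.amplitude_handling not in ("fit_amplitude", "fixed_mass_alpha"):
            raise InvalidInputError(
                f"unknown amplitude handling {self.amplitude_handling!r}")
        if self.amplitude_handling == "fixed_mass_alpha" and not self.mass:
            raise InvalidInputError("fixed_mass_alpha requires the injected mass")
        if self.loss != "least_squares":
            raise InvalidInputError(f"unsupported loss {self.loss!r}")


@dataclass
class FitResult:
    """Estimates and diagnostics from one fit."""

    d_x: float
    d_y: float
    d_z: float
    k: float
    amplitude: float                 # lumped A = M/alpha, nmol
    alpha: float | None              # only under fixed_mass_alpha
    average_d: float
    average_convention: str
    t_half: float | None
    tortuosity: float | None
    stderr: dict                     # per-parameter standard errors
    rss: float
    n_samples: int
    converged: bool
    n_starts_used: int
    seed: int
    warnings: list = field(default_factory=list)

    @property
    def params(self) -> DiffusionParameters:
        return DiffusionParameters(d_x=self.d_x, d_y=self.d_y, d_z=self.d_z,
                                   k=self.k, alpha=self.alpha or 1.0)

    def to_dict(self) -> dict:
        return {
            "estimates": {
                "d_x_mm2_per_s": self.d_x, "d_y_mm2_per_s": self.d_y,
                "d_z_mm2_per_s": self.d_z, "k_per_s": self.k,
                "amplitude_nmol": self.amplitude, "alpha": self.alpha,
            },
            "derived": {
                "average_d_mm2_per_s": self.average_d,
                "average_convention": self.average_convention,
                "t_half_s": self.t_half,
                "tortuosity": self.tortuosity,
            },
            "stderr": self.stderr,
            "diagnostics": {
                "rss": self.rss, "n_samples": self.n_samples,
                "converged": self.converged, "n_starts_used": self.n_starts_used,
                "seed": self.seed, "warnings": list(self.warnings),
            },
        }

    def save(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [
            "Diffusion-clearance fit",
            f"  Dx = {self.d_x:.4e} mm^2/s (SE {self.stderr.get('d_x', float('nan')):.2e})",
            f"  Dy = {self.d_y:.4e} mm^2/s (SE {self.stderr.get('d_y', float('nan')):.2e})",
            f"  Dz = {self.d_z:.4e} mm^2/s (SE {self.stderr.get('d_z', float('nan')):.2e})",
            f"  k  = {self.k:.4e} 1/s    (SE {self.stderr.get('k', float('nan')):.2e})",
            f"  A  = {self.amplitude:.4e} nmol (M/alpha)",
            f"  average D ({self.average_convention}) = {self.average_d:.4e} mm^2/s",
        ]
        if self.t_half is not None:
            lines.append(f"  t_1/2 = {self.t_half:.4e} s")
        if self.alpha is not None:
            lines.append(f"  alpha = {self.alpha:.4f}")
        if self.tortuosity is not None:
            lines.append(f"  lambda = {self.tortuosity:.3f}")
        lines.append(f"  RSS = {self.rss:.4e} over {self.n_samples} samples; "
                     f"converged={self.converged}")
        return "\n".join(lines)


def _validate_samples(samples: SpacetimeSampleSet) -> None:
    if len(samples) < MIN_SAMPLES:
        raise InsufficientDataError(
            f"{len(samples)} samples supplied; the model requires more than five "
            "measurement groups (>= 6)")
    if samples.n_times < 2:
        raise InsufficientDataError("samples must span at least 2 distinct times")
    if samples.n_positions < 2:
        raise InsufficientDataError("samples must span at least 2 distinct positions")


def _predict(theta: np.ndarray, x, y, z, t) -> np.ndarray:
    dx, dy, dz = np.exp(theta[:3])
    k = theta[3]
    amp = np.exp(theta[4])
    p = DiffusionParameters(d_x=dx, d_y=dy, d_z=dz, k=max(k, 0.0), alpha=1.0)
    return amp * point_source_kernel(p, x, y, z, t)


def _auto_guess(samples: SpacetimeSampleSet) -> np.ndarray:
    """Moment-based initial guess.

    Per-axis D from the growth of the concentration-weighted second moment
    between the two widest-separated frames (for a Gaussian cloud,
    <x_a^2> = 2 D_a t); k from the log-linear decay of the per-frame peak
    corrected for the t^{-3/2} spreading factor; amplitude from the
    earliest-frame peak inverted through the closed form.
    """
    df = samples.data
    ts = np.sort(df["t_s"].unique())
    t1, t2 = ts[0], ts[-1]

    def m2(tval, col):
        sub = df[df["t_s"] == tval]
        w = sub["conc_mM"].to_numpy()
        v = sub[col].to_numpy()
        return float(np.sum(w * v * v) / np.sum(w))

    d0 = np.empty(3)
    for a, col in enumerate(("x_mm", "y_mm", "z_mm")):
        growth = (m2(t2, col) - m2(t1, col)) / (2.0 * (t2 - t1))
        if not np.isfinite(growth) or growth <= 0:
            growth = m2(t2, col) / (2.0 * t2)
        d0[a] = np.clip(growth, 1e-6, 1e-2)

    peaks = np.array([df[df["t_s"] == tv]["conc_mM"].max() for tv in ts])
    if ts.size >= 2 and np.all(peaks > 0):
        slope = np.polyfit(ts, np.log(peaks * ts**1.5), 1)[0]
        k0 = float(np.clip(-slope, 0.0, 1e-3))
    else:
        k0 = 1e-5

    sub = df[df["t_s"] == t1]
    i = int(sub["conc_mM"].idxmax())
    row = df.loc[i]
    quad = sum(row[c] ** 2 / (4 * d0[a] * t1) for a, c in
               enumerate(("x_mm", "y_mm", "z_mm")))
    a0 = (row["conc_mM"] * 8 * (np.pi * t1) ** 1.5 * np.sqrt(np.prod(d0))
          * np.exp(k0 * t1 + min(quad, 50.0)))
    a0 = float(np.clip(a0, *_A_BOUNDS))
    return np.array([*np.log(d0), k0, np.log(a0)])


def _stderrs(theta: np.ndarray, jac: np.ndarray, rss: float, n: int,
             convention: str) -> tuple[dict, list]:
    """Delta-method standard errors on the natural scale.

    sigma^2 = RSS/(n-p); cov_theta = sigma^2 (J'J)^{-1}.  For log-fitted
    parameters SE(p) = p * SE(log p); for the average D the gradient with
    respect to (log Dx, log Dy, log Dz) is propagated through cov_theta.
    """
    notes = []
    p = theta.size
    dof = max(n - p, 1)
    sigma2 = rss / dof
    jtj = jac.T @ jac
    try:
        cond = np.linalg.cond(jtj)
        if cond > 1e12:
            notes.append("identifiability: Jacobian nearly rank-deficient "
                         f"(cond {cond:.2e}); standard errors unreliable")
        cov = sigma2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        notes.append("identifiability: singular Jacobian; standard errors unavailable")
        return {k: float("nan") for k in
                ("d_x", "d_y", "d_z", "k", "amplitude", "average_d")}, notes

    se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    dx, dy, dz = np.exp(theta[:3])
    amp = np.exp(theta[4])
    out = {
        "d_x": dx * se_theta[0],
        "d_y": dy * se_theta[1],
        "d_z": dz * se_theta[2],
        "k": se_theta[3],
        "amplitude": amp * se_theta[4],
    }
    # gradient of the average D w.r.t. (log Dx, log Dy, log Dz)
    d = np.array([dx, dy, dz])
    if convention == "rss":
        dbar = float(np.sqrt(np.sum(d**2)))
        grad = d**2 / dbar
    elif convention == "rms":
        dbar = float(np.sqrt(np.mean(d**2)))
        grad = d**2 / (3.0 * dbar)
    else:  # mean
        grad = d / 3.0
    g = np.zeros(p)
    g[:3] = grad
    out["average_d"] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    return out, notes


def fit(samples: SpacetimeSampleSet, options: FitOptions | None = None) -> FitResult:
    """Fit (Dx, Dy, Dz, k, A) to spacetime concentration samples.

    Requires at least 6 samples spanning at least 2 distinct times and
    positions.  Runs a bounded trust-region least-squares from the auto
    initial guess plus ``multistart - 1`` seeded perturbations and returns
    the best converged solution.
    """
    options = options or FitOptions()
    _validate_samples(samples)
    xyzt = samples.xyzt
    x, y, z, t = xyzt[:, 0], xyzt[:, 1], xyzt[:, 2], xyzt[:, 3]
    c = samples.conc

    if options.initial == "auto":
        theta0 = _auto_guess(samples)
    else:
        ini = options.initial
        theta0 = np.array([np.log(ini["d_x"]), np.log(ini["d_y"]),
                           np.log(ini["d_z"]), ini["k"], np.log(ini["amplitude"])])

    lo = np.array([np.log(_D_BOUNDS[0])] * 3 + [_K_BOUNDS[0], np.log(_A_BOUNDS[0])])
    hi = np.array([np.log(_D_BOUNDS[1])] * 3 + [_K_BOUNDS[1], np.log(_A_BOUNDS[1])])
    theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)

    def resid(theta):
        return _predict(theta, x, y, z, t) - c

    rng = np.random.default_rng(options.seed)
    starts = [theta0]
    for _ in range(max(options.multistart - 1, 0)):
        pert = theta0.copy()
        pert[[0, 1, 2, 4]] += rng.uniform(-np.log(3.0), np.log(3.0), size=4)
        pert[3] *= np.exp(rng.uniform(-np.log(3.0), np.log(3.0)))
        starts.append(np.clip(pert, lo + 1e-9, hi - 1e-9))

    best = None
    n_used = 0
    for s in starts:
        n_used += 1
        res = least_squares(resid, s, bounds=(lo, hi), method="trf",
                            xtol=options.tolerance, ftol=options.tolerance,
                            gtol=options.tolerance, max_nfev=options.max_iterations * 6,
                            x_scale="jac")
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise NumericalError("no multistart converged to a finite solution")

    theta = best.x
    rss = float(2.0 * best.cost)
    notes = []
    converged = bool(best.status > 0)
    if not converged:
        notes.append(f"optimizer stopped without meeting tolerances (status {best.status})")

    se, se_notes = _stderrs(theta, best.jac, rss, len(samples),
                            options.average_convention)
    notes.extend(se_notes)

    # boundary-solution flag
    at_bound = np.isclose(theta, lo, atol=1e-6) | np.isclose(theta, hi, atol=1e-6)
    if np.any(at_bound):
        notes.append("one or more parameters at an optimisation bound")

    dx, dy, dz = np.exp(theta[:3])
    k = float(theta[3])
    amp = float(np.exp(theta[4]))
    alpha = None
    if options.amplitude_handling == "fixed_mass_alpha":
        alpha = float(options.mass / amp)
        if not (0 < alpha <= 1):
            notes.append(f"implied alpha {alpha:.4g} outside (0, 1]")

    dparams = DiffusionParameters(d_x=dx, d_y=dy, d_z=dz, k=max(k, 0.0), alpha=1.0)
    avg = average_diffusion(dparams, options.average_convention)
    lam = None
    if options.d_free is not None:
        lam = float(np.sqrt(options.d_free /
                            average_diffusion(dparams, "rms")))
    return FitResult(
        d_x=float(dx), d_y=float(dy), d_z=float(dz), k=k, amplitude=amp,
        alpha=alpha, average_d=avg, average_convention=options.average_convention,
        t_half=half_life(k) if k > 0 else None, tortuosity=lam, stderr=se,
        rss=rss, n_samples=len(samples), converged=converged,
        n_starts_used=n_used, seed=options.seed, warnings=notes,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo recovery harness


def _rep_seed(seed: int, rep: int) -> int:
    """Deterministic per-replicate seed depending only on (seed, rep), so
    sweeps over other settings share noise draws (common random numbers)."""
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))


def run_pipeline(truth, noise_seed: int | None = None,
                 fit_options: FitOptions | None = None,
                 max_samples: int = 3000) -> FitResult:
    """phantom -> subtract -> calibrate -> extract -> fit, for one realisation."""
    from .phantom import generate_phantom

    if noise_seed is not None:
        truth = replace(truth, noise=replace(truth.noise, seed=noise_seed))
    series, _ = generate_phantom(truth)
    dsi = subtract_series(series)
    sd = estimate_background_sd(dsi[0])
    conc = [signal_to_concentration(d, truth.calibration)[0] for d in dsi]
    samples = extract_samples(
        conc, series.times, series.affine, truth.source.position,
        release_time=getattr(truth.source, "release_time", 0.0),
        threshold="auto", background_sd=sd * truth.calibration.kappa,
        max_samples=max_samples,
        rng=np.random.default_rng(truth.noise.seed),
    )
    return fit(samples, fit_options or FitOptions(seed=truth.noise.seed))


def recovery_experiment(truth, n_reps: int = 25, seed: int = 0,
                        fit_options: FitOptions | None = None) -> pd.DataFrame:
    """Repeat the full pipeline with independent noise and score recovery.

    Returns one row per replicate with the estimates, their relative errors
    against the truth, and the replicate seed.  Fit failures are recorded
    (``ok = False``) rather than aborting.
    """
    if n_reps < 2:
        raise InvalidInputError("recovery experiment needs n_reps >= 2")
    truth_vals = {
        "d_x": truth.params.d_x, "d_y": truth.params.d_y,
        "d_z": truth.params.d_z, "k": truth.params.k,
        "amplitude": truth.source.mass / truth.params.alpha,
    }
    rows = []
    for rep in range(n_reps):
        rs = _rep_seed(seed, rep)
        row = {"rep": rep, "seed": rs, "ok": True}
        try:
            r = run_pipeline(truth, noise_seed=rs, fit_options=fit_options)
            est = {"d_x": r.d_x, "d_y": r.d_y, "d_z": r.d_z, "k": r.k,
                   "amplitude": r.amplitude}
            row.update({f"{p}_hat": v for p, v in est.items()})
            row["average_d_hat"] = r.average_d
            for p, v in est.items():
                tv = truth_vals[p]
                row[f"{p}_relerr"] = (v - tv) / tv if tv else np.nan
                sep = r.stderr.get(p, np.nan)
                row[f"{p}_covered"] = bool(abs(v - tv) <= 1.96 * sep) if np.isfinite(sep) else False
            row["converged"] = r.converged
        except Exception as e:  # noqa: BLE001 — failure rate is part of the result
            row["ok"] = False
            row["error"] = str(e)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter bias, relative RMSE, median |relative error| and
    coverage of nominal 95% intervals, over successful replicates."""
    ok = table[table["ok"]]
    out = []
    for p in ("d_x", "d_y", "d_z", "k", "amplitude"):
        rel = ok[f"{p}_relerr"].to_numpy(dtype=float)
        out.append({
            "parameter": p,
            "bias_rel": float(np.mean(rel)),
            "rmse_rel": float(np.sqrt(np.mean(rel**2))),
            "median_abs_rel_err": float(np.median(np.abs(rel))),
            "coverage_95": float(ok[f"{p}_covered"].mean()),
            "n_ok": int(len(ok)),
            "failure_rate": float(1.0 - len(ok) / len(table)),
        })
    return pd.DataFrame(out)


def fit_roi_tiles(conc_frames, times, affine, source_position,
                  tiling: tuple[int, int] = (2, 2),
                  options: FitOptions | None = None,
                  threshold: float | str = "auto",
                  exclusion_radius: float = 0.5) -> dict:
    """Independent fits on an (nx, ny) tiling of the x-y plane (full z extent).

    Returns ``{(i_centre, j_centre): FitResult}`` for tiles with enough
    samples; tiles failing the 6-sample minimum are skipped with a warning.
    Feeds :func:`issdiff.imaging.render_parameter_map`.
    """
    shape = np.asarray(conc_frames[0]).shape
    nx, ny = tiling
    xs = np.linspace(0, shape[0], nx + 1).astype(int)
    ys = np.linspace(0, shape[1], ny + 1).astype(int)
    results = {}
    for a in range(nx):
        for b in range(ny):
            masked = []
            for f in conc_frames:
                m = np.zeros_like(np.asarray(f, dtype=float))
                m[xs[a]:xs[a + 1], ys[b]:ys[b + 1], :] = \
                    np.asarray(f, dtype=float)[xs[a]:xs[a + 1], ys[b]:ys[b + 1], :]
                masked.append(m)
            key = (int(xs[a] + xs[a + 1]) // 2, int(ys[b] + ys[b + 1]) // 2)
            try:
                samples = extract_samples(masked, times, affine, source_position,
                                          threshold=threshold,
                                          exclusion_radius=exclusion_radius)
                results[key] = fit(samples, options)
            except InsufficientDataError as e:
                warnings.warn(f"tile {key}: skipped ({e})", stacklevel=2)
    if not results:
        warnings.warn("all tiles skipped; empty parameter map", stacklevel=2)
    return results
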
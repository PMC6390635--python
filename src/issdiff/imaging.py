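"""Image-side pipeline: NIfTI I/O, pre/post subtraction, signal-to-
concentration calibration, spacetime sample extraction and parameter maps.

The tracer-MRI workflow is: acquire one pre-injection volume and a series of
post-injection volumes; subtract pre from each post to get the signal
increment dSI; convert dSI to tracer concentration with a linear calibration
``C = kappa * dSI``; then collect (x, y, z, t, C) samples around the
injection site for parameter fitting.

Conventions: voxel-centre, 0-based indexing; world coordinates come from the
NIfTI header affine; sample coordinates are stored relative to the declared
source position so they live in the model frame.  Inputs are assumed
co-registered -- ``register`` is a pass-through hook that only warns when
headers disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, InvalidInputError

__all__ = [
    "ImageSeries",
    "Calibration",
    "SpacetimeSampleSet",
    "register",
    "subtract_series",
    "signal_to_concentration",
    "extract_samples",
    "read_image",
    "write_image",
    "read_samples",
    "write_samples",
    "render_parameter_map",
]

SAMPLE_COLUMNS = ["x_mm", "y_mm", "z_mm", "t_s", "conc_mM"]


@dataclass
class ImageSeries:
    """A pre-injection volume plus post-injection volumes at known times.

    ``affine`` maps 0-based voxel indices to world mm (voxel centres).
    """

    pre: np.ndarray
    posts: list[np.ndarray]
    times: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.posts = [np.asarray(p, dtype=float) for p in self.posts]
        self.times = np.asarray(self.times, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.pre.ndim != 3:
            raise InvalidInputError("pre image must be 3-D")
        for p in self.posts:
            if p.shape != self.pre.shape:
                raise InvalidInputError("all post frames must match the pre image shape")
        if self.times.size != len(self.posts):
            raise InvalidInputError("one acquisition time per post frame required")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("acquisition times must be strictly increasing")
        if self.affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]


@dataclass(frozen=True)
class Calibration:
    """Linear signal-increment-to-concentration map: C = kappa * dSI.

    ``kappa``: mM per signal unit (> 0).  ``valid_range``: the dSI interval
    over which linearity is trusted; values outside are flagged, not altered.
    """

    kappa: float
    valid_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise InvalidInputError(f"kappa must be > 0, got {self.kappa!r}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise InvalidInputError("valid_range must be an increasing interval")

    def to_dict(self) -> dict:
        lo, hi = self.valid_range
        return {
            "kappa_mM_per_SU": self.kappa,
            "valid_range_SU": [float(lo), None if np.isinf(hi) else float(hi)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        lo, hi = d.get("valid_range_SU", [0.0, None])
        return cls(kappa=float(d["kappa_mM_per_SU"]),
                   valid_range=(float(lo), np.inf if hi is None else float(hi)))


@dataclass
class SpacetimeSampleSet:
    """(x, y, z, t, C) rows in the source-centred model frame.

    ``data`` has columns ``x_mm, y_mm, z_mm, t_s, conc_mM``; ``provenance``
    optionally records the originating voxel indices and frame numbers.
    """

    data: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"sample table missing columns {missing}")
        d = self.data
        if not np.all(np.isfinite(d[SAMPLE_COLUMNS].to_numpy())):
            raise InvalidInputError("sample table contains non-finite values")
        if np.any(d["t_s"].to_numpy() <= 0):
            raise InvalidInputError("all sample times must be > 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xyzt(self) -> np.ndarray:
        return self.data[["x_mm", "y_mm", "z_mm", "t_s"]].to_numpy()

    @property
    def conc(self) -> np.ndarray:
        return self.data["conc_mM"].to_numpy()

    @property
    def n_times(self) -> int:
        return int(self.data["t_s"].nunique())

    @property
    def n_positions(self) -> int:
        return int(self.data[["x_mm", "y_mm", "z_mm"]].drop_duplicates().shape[0])


def register(series: ImageSeries, reference_affine: np.ndarray | None = None) -> ImageSeries:
    """Pass-through registration hook.

    Inputs are assumed rigidly co-registered upstream; this hook exists so a
    real aligner can be slotted in.  Warns if the series affine disagrees
    with ``reference_affine``.
    """
    if reference_affine is not None and not np.allclose(series.affine, reference_affine):
        warnings.warn("pre/post affines disagree; images are used as-is "
                      "(registration is a pass-through hook)", stacklevel=2)
    return series


def subtract_series(series: ImageSeries) -> list[np.ndarray]:
    """Per-frame voxelwise post - pre signal increment (dSI).

    Negative values (noise) are retained at this stage; clamping to the
    physical C >= 0 happens after calibration.
    """
    return [post - series.pre for post in series.posts]


def signal_to_concentration(
    delta_si: np.ndarray, cal: Calibration
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a dSI array to concentration (mM): ``C = kappa * dSI``.

    Returns ``(conc, out_of_range)``: concentrations with negatives clamped
    to 0, and a boolean mask flagging dSI values outside the calibration's
    linear range.
    """
    delta_si = np.asarray(delta_si, dtype=float)
    lo, hi = cal.valid_range
    mask = (delta_si < lo) | (delta_si > hi)
    conc = np.clip(cal.kappa * delta_si, 0.0, None)
    return conc, mask


def estimate_background_sd(delta_si: np.ndarray, corner_fraction: float = 0.15) -> float:
    """SD of dSI in the eight corner sub-cubes (assumed tracer-free), used
    for the default extraction threshold."""
    delta_si = np.asarray(delta_si, dtype=float)
    n = [max(1, int(corner_fraction * s)) for s in delta_si.shape]
    corners = []
    for sx in (slice(0, n[0]), slice(-n[0], None)):
        for sy in (slice(0, n[1]), slice(-n[1], None)):
            for sz in (slice(0, n[2]), slice(-n[2], None)):
                corners.append(delta_si[sx, sy, sz].ravel())
    return float(np.std(np.concatenate(corners)))


MIN_SAMPLES = 6  # estimation requires more than five measurement groups


def extract_samples(
    conc_frames: list[np.ndarray],
    times,
    affine: np.ndarray,
    source_position,
    release_time: float = 0.0,
    threshold: float | str = "auto",
    background_sd: float | None = None,
    max_samples: int | None = 4000,
    exclusion_radius: float = 0.5,
    rng: np.random.Generator | None = None,
) -> SpacetimeSampleSet:
    """Collect (x, y, z, t, C) samples from a concentration series.

    Voxels with concentration above ``threshold`` are emitted, excluding
    those within ``exclusion_radius`` mm of the source (needle-track /
    near-field guard).  Coordinates are voxel centres (via the affine)
    re-expressed relative to ``source_position``; times are relative to
    ``release_time``.  ``threshold="auto"`` uses 3x the background SD
    (supplied, or estimated from the first frame's corners).  When more than
    ``max_samples`` voxels qualify, a seeded uniform subsample is taken.

    Raises :class:`InsufficientDataError` with fewer than 6 qualifying rows.
    """
    times = np.asarray(times, dtype=float)
    affine = np.asarray(affine, dtype=float)
    source_position = np.asarray(source_position, dtype=float)
    if len(conc_frames) != times.size:
        raise InvalidInputError("one time per concentration frame required")

    if threshold == "auto":
        sd = background_sd
        if sd is None:
            sd = estimate_background_sd(conc_frames[0])
        threshold = 3.0 * sd
    threshold = float(threshold)

    rows = []
    prov = []
    for f, (frame, t_abs) in enumerate(zip(conc_frames, times)):
        frame = np.asarray(frame, dtype=float)
        idx = np.argwhere(frame > threshold)
        if idx.size == 0:
            continue
        world = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
        rel = world - source_position
        r = np.linalg.norm(rel, axis=1)
        keep = r >= exclusion_radius
        if not np.any(keep):
            continue
        rel = rel[keep]
        vals = frame[tuple(idx[keep].T)]
        t_rel = t_abs - release_time
        block = np.column_stack([rel, np.full(rel.shape[0], t_rel), vals])
        rows.append(block)
        prov.append(np.column_stack([idx[keep], np.full(rel.shape[0], f, dtype=int)]))

    if not rows:
        raise InsufficientDataError(
            f"no voxels above threshold {threshold:.4g} outside the exclusion radius"
        )
    table = np.vstack(rows)
    prov_table = np.vstack(prov)
    if table.shape[0] < MIN_SAMPLES:
        raise InsufficientDataError(
            f"only {table.shape[0]} qualifying samples; at least {MIN_SAMPLES} required"
        )
    if max_samples is not None and table.shape[0] > max_samples:
        rng = rng or np.random.default_rng(0)
        sel = np.sort(rng.choice(table.shape[0], size=max_samples, replace=False))
        table = table[sel]
        prov_table = prov_table[sel]

    data = pd.DataFrame(table, columns=SAMPLE_COLUMNS)
    provenance = pd.DataFrame(prov_table, columns=["i", "j", "k", "frame"])
    return SpacetimeSampleSet(data=data, provenance=provenance)


# ---------------------------------------------------------------------------
# File I/O


def write_image(path, array: np.ndarray, affine: np.ndarray) -> None:
    """Write a 3-D or 4-D volume as NIfTI with the given voxel-to-world affine."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), np.asarray(affine, float))
    nib.save(img, str(path))


def read_image(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (array, affine)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, float)
    except Exception as e:  # nibabel raises various types for corrupt files
        raise FormatError(f"could not read NIfTI file {path}: {e}") from e


def write_samples(path, samples: SpacetimeSampleSet) -> None:
    """Write a sample set as CSV with header x_mm,y_mm,z_mm,t_s,conc_mM."""
    samples.data[SAMPLE_COLUMNS].to_csv(path, index=False)


def read_samples(path) -> SpacetimeSampleSet:
    """Read a sample CSV; validates schema and invariants."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sample file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample CSV {path} missing required columns: {missing}")
    arr = df[SAMPLE_COLUMNS].to_numpy()
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"sample CSV {path}: non-finite value in field "
                          f"{SAMPLE_COLUMNS[int(np.argwhere(~np.isfinite(arr))[0][1])]}")
    if np.any(df["t_s"].to_numpy() <= 0):
        raise FormatError(f"sample CSV {path}: field t_s must be > 0 in every row")
    return SpacetimeSampleSet(data=df[SAMPLE_COLUMNS].copy())


def render_parameter_map(
    tile_results,
    base_image: np.ndarray,
    out_path,
    parameter: str = "average_d",
    slice_axis: int = 2,
    slice_index: int | None = None,
    levels: int = 8,
) -> bool:
    """Render a contour map of per-tile fitted parameters over a grayscale base.

    ``tile_results`` maps tile centre voxel indices (i, j) in the displayed
    plane to fitted values (see ``estimation.fit_roi_tiles``).  Returns True
    if a map was drawn, False (with a warning) when no tile converged.
    Purely presentational; values come from the estimation module.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base_image = np.asarray(base_image, dtype=float)
    if slice_index is None:
        slice_index = base_image.shape[slice_axis] // 2
    base2d = np.take(base_image, slice_index, axis=slice_axis)

    entries = [(ij, v) for ij, v in tile_results.items() if np.isfinite(v)]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(base2d.T, cmap="gray", origin="lower")
    drew = False
    if not entries:
        warnings.warn("no converged tiles; writing base image without contours",
                      stacklevel=2)
    else:
        ii = np.array([ij[0] for ij, _ in entries], dtype=float)
        jj = np.array([ij[1] for ij, _ in entries], dtype=float)
        vv = np.array([v for _, v in entries], dtype=float)
        if len(entries) >= 4 and np.ptp(vv) > 0:
            from scipy.interpolate import griddata
            gi, gj = np.meshgrid(
                np.linspace(ii.min(), ii.max(), 50),
                np.linspace(jj.min(), jj.max(), 50), indexing="ij")
            gv = griddata((ii, jj), vv, (gi, gj), method="linear")
            cs = ax.contour(gi, gj, gv, levels=levels, cmap="viridis")
            ax.clabel(cs, inline=True, fontsize=6, fmt="%.2e")
        else:
            sc = ax.scatter(ii, jj, c=vv, cmap="viridis", s=80, marker="s")
            fig.colorbar(sc, ax=ax, shrink=0.8)
        drew = True
    ax.set_title(parameter)
    ax.set_xlabel("i (voxel)")
    ax.set_ylabel("j (voxel)")
    fig.savefig(out_path, dpi=100, metadata={"Software": "issdiff"})
    plt.close(fig)
    return drew
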
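"""Regional fits and a contour parameter map.

Tiles the field of view, fits each tile independently and renders the
average-D contour map over a grayscale base frame, mirroring how regional
diffusivity is visualised on top of the anatomy.
"""

from dataclasses import replace
from pathlib import Path

from issdiff import (
    NoiseModel,
    default_truth,
    fit_roi_tiles,
    generate_phantom,
    render_parameter_map,
    signal_to_concentration,
    subtract_series,
)

truth = replace(default_truth(seed=0), noise=NoiseModel(kind="none"))
series, truth = generate_phantom(truth)
dsi = subtract_series(series)
conc = [signal_to_concentration(d, truth.calibration)[0] for d in dsi]

tiles = fit_roi_tiles(conc, series.times, series.affine,
                      truth.source.position, tiling=(2, 2), threshold=1e-6)
for key, r in tiles.items():
    print(f"tile centred at voxel {key}: average D = {r.average_d:.3e} mm^2/s")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "parameter_map.png"
render_parameter_map({k: r.average_d for k, r in tiles.items()},
                     series.posts[0], path)
print(f"\nmap written to {path}; the phantom is homogeneous, so all tiles "
      "agree — on real data the contours trace regional anisotropy.")
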
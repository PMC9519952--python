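"""Build average-lifetime maps from a raster scan of fluorescence decays.

Generates a synthetic scan with two lifetime patches on a uniform base,
reconstructs the per-pixel average lifetime, and reports region-of-
interest statistics.
"""

import numpy as np

from tissueqc import flim, synthetic as syn

# a 24x24 pixel scan (20 µm pitch): base tissue at 4.0 ns with a 5.2 ns
# and a 3.1 ns patch, Poisson photon noise, 400 ps IRF
spec = syn.FlimPhantomSpec(
    shape=(24, 24),
    base_lifetime=4.0,
    patches=((8.0, 8.0, 5.0, 5.2), (17.0, 17.0, 4.0, 3.1)),
    noise="poisson",
    peak_counts=20000,
    background_margin=2,
    seed=7,
)
scan, truth = syn.gen_flim_phantom(spec)

lt_map = flim.build_lifetime_map(scan, pre_window=(0, 25))
(cy, cx), r = flim.auto_roi(lt_map)
stats = flim.roi_statistics(lt_map, (cy, cx), r)

print(f"map: {lt_map.grid.shape[0]}x{lt_map.grid.shape[1]} px, "
      f"{np.isnan(lt_map.grid).sum()} low-signal px (zero-signal border)")
print(f"whole-map mean lifetime: {np.nanmean(lt_map.grid):.3f} ns "
      f"(true pixel-average {np.nanmean(truth):.3f} ns)")
print(f"auto ROI at ({cy:.0f},{cx:.0f}) r={r:.1f} px: "
      f"mean {stats.mean_lt:.3f} ns, sd {stats.sd_lt:.3f} ns over {stats.n_pixels} px")
# the mean tracks the true average lifetime; the SD reflects the mixture
# of patch lifetimes inside the ROI, not photon noise (which is ~1%)
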
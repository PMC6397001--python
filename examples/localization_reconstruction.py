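"""From a single-molecule image stack to a filtered localization map.

Renders a small spot stack with Poisson photon statistics, detects and
fits each spot with a 2D Gaussian, drops localizations below the
800-photon cut, and bins the survivors into a 20 nm reconstruction.
"""

import numpy as np

import nanocoloc as nc
from nanocoloc import localization as loc

spec = nc.SpotImageSpec(
    n_frames=40,
    emitters=[(800.0, 800.0, 2500.0), (2200.0, 1500.0, 1200.0), (1400.0, 2600.0, 600.0)],
    background=10.0,
    field_width_nm=3200.0,
    field_height_nm=3200.0,
    seed=5,
)
stack = nc.render_spot_stack(spec)
table = loc.localize_stack(stack, spec.camera_pixel_nm, psf_sigma_prior_nm=spec.psf_sigma_nm)
kept = loc.filter_by_photons(table)  # N >= 800

print(f"raw localizations      : {len(table)}")
print(f"after 800-photon filter: {len(kept)}")
print(f"median precision       : {kept.records['uncertainty [nm]'].median():.1f} nm "
      "(DLR/sqrt(N) model)")

reco = loc.render_localization_map(kept, pixel_size_nm=20.0)
print(f"reconstruction         : {reco.shape[1]}x{reco.shape[0]} px, "
      f"{int(reco.sum())} localizations binned")
# The 600-photon emitter largely disappears after the photon cut, while the
# bright emitters localize to a few-nm precision around their true positions.
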
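"""Monte-Carlo transport against diffusion theory.

Runs a modest homogeneous transport (mu_a = 0.2 /cm, mu_s' = 5 /cm, g = 0.9)
and compares the total diffuse reflectance and the detector-level quantities
with the semi-infinite diffusion closed forms.
"""

import numpy as np

from uotcnr import total_diffuse_reflectance, run_transport
from uotcnr.config import StudyConfig
from uotcnr.diffusion import DiffusionLevelModel

cfg = StudyConfig()
phantom, scan_A, scan_B = cfg.scans(1.0, contrast=1.0)

res = run_transport(phantom, scan_B, n_packets=200_000, seed=42)
conservation = (
    res.detected_weight + res.absorbed_weight + res.escaped_elsewhere_weight
) / res.launched_weight
print(f"weight conservation: {conservation:.9f} (should be 1)")

mc_r = res.total_reflected_weight / res.n_packets
th_r = total_diffuse_reflectance(0.2, 5.0)
print(f"total diffuse reflectance: MC {mc_r:.4f} vs diffusion {th_r:.4f} "
      f"({100 * (mc_r / th_r - 1):+.1f}%)")

model = DiffusionLevelModel(phantom, scan_A, scan_B)
print(f"untagged density at detector (per photon, /cm^2): "
      f"MC {res.untagged_transmittance_per_area:.3e} vs diffusion {model.untagged():.3e}")
print(f"in-voxel path integral at z=1 cm (per photon, /cm): "
      f"MC {res.path_weight_per_area:.3e} vs diffusion {model.tagged_weights()[1]:.3e}")
# The path integral is the raw material for acousto-optic tagging: multiplying
# it by the tagged fraction per cm of in-voxel path gives the tagged photon
# density at the detector.
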
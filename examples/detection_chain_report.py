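"""Derived detection-chain quantities of the imaging example.

Prints the collection-angle loss, per-method detection efficiencies, speckle
count in the collection area, the laser-safety photon budget and the camera
data rate.  These are the fixed constants that feed the CNR models.
"""

from uotcnr import (
    camera_data_rate,
    detection_efficiency,
    filter_attenuation_db,
    na_collection_loss,
    safety_photon_budget,
    speckles_in_area,
)
from uotcnr.config import StudyConfig, default_variants

cfg = StudyConfig()

print(f"collection loss at NA=0.7 (exact NA^2): {na_collection_loss(0.7):.3f}")
for name, det in default_variants(cfg).items():
    print(f"  eta_det[{name:9s}] = {detection_efficiency(det):.3f}")
print(f"speckles in 1 cm^2 at 600 nm, NA 0.7: {speckles_in_area(1, 600, 0.7):.2e}")
print(f"safety budget, 300 mW/cm^2 x 1 cm^2 x 1 s: {safety_photon_budget():.2e} photons")
print(f"  per voxel over a 30x30 image: {safety_photon_budget(n_regions=900):.2e}")
print(f"camera data rate, 1 Mpx / 12 bit / 1 kfps: {camera_data_rate(10**6):.2e} B/s")
print(f"Tm-doped filter, 15 /cm over 1.2 cm: {filter_attenuation_db(15, 1.2):.1f} dB")

# What the numbers mean: the single-detector methods (SHB, PR) collect ~1.7e8
# speckles over 1 cm^2, the cameras only N_px/n; 1e15 photons may be spent per
# voxel within the skin exposure limit; a kHz 1 Mpx camera already streams
# 1.5 GB/s of raw holograms.
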
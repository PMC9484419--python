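# uotcnr

Contrast-to-noise modelling for **ultrasound optical tomography (UOT)**: how
deep into tissue can each of four detection methods distinguish an absorbing
inclusion?

In UOT a focused ultrasound pulse frequency-shifts ("tags") a small fraction
of the diffuse laser light crossing its focal volume, localizing optical
absorption centimetres deep in scattering tissue.  Detecting the weak tagged
light over the untagged background is the hard part, and several competing
detection methods exist.  This package implements, as a tested pipeline, a
shot-noise-limited comparison of four of them:

| method | code | detection principle |
|---|---|---|
| spectral hole burning | `SHB` | cryogenic rare-earth crystal band-pass filter, large-area detector |
| photorefractive | `PR` | adaptive holography in a photorefractive crystal, single-element detector |
| off-axis holography | `HOL` | single-shot camera interferogram, Fourier-side-band reconstruction |
| speckle contrast | `SC` | ultrasound-induced blur of the camera speckle pattern |

The comparison metric is the contrast-to-noise ratio between two probe
positions (A: background, B: inside the inclusion),

```
CNR = |S_A - S_B| / sqrt(sigma_A^2 + sigma_B^2),
```

evaluated per method from the tagged / untagged photon densities N_T,A,
N_T,B and N_U, e.g. for spectral hole burning

```
CNR_SHB = sqrt(2 S eta_det) |N_T,A - N_T,B| / sqrt(N_T,A + N_T,B + T_U N_U)
```

with collection area S, detection efficiency eta_det and filter leak T_U.
Photon levels come from weighted Monte-Carlo photon transport through a
muscle-like phantom (mu_s' = 5 /cm, g = 0.9, mu_a = 0.2 /cm at 800 nm) with
a 3x3x3 mm^3 inclusion, acousto-optic tagging in a 3x3x3 mm^3, 2 MPa
ultrasound voxel, and a diffusion-theory depth extrapolation calibrated once
at a shallow reference depth (see `docs/methods.md`).  The headline output
is the **maximal imaging depth** - the depth where CNR drops to 1 - for
every detection variant, for the full laser-safety photon budget of 1e15
input photons per voxel.

## Worked example

```python
from uotcnr import scan_depth
from uotcnr.config import StudyConfig

result = scan_depth(StudyConfig(), n_packets=300_000, seed=3)
for variant, crossing in result.crossings().items():
    print(f"{variant:10s} {crossing.depth:5.2f} +- {crossing.err:.2f} cm")
```

prints (also available as `python examples/depth_scan_small.py`):

```
SHB_30dB     3.31 +- 0.05
SHB_80dB     4.71 +- 0.07
PR_0.10      1.98 +- 0.06
PR_0.35      2.26 +- 0.05
HOL_1Mpx     1.60 +- 0.05
HOL_50Mpx    2.15 +- 0.04
SC_1Mpx      0.86 +- 0.07
SC_50Mpx     1.54 +- 0.05
```

Each line is the depth (cm) at which that detection variant's CNR falls to
1 for an absorption contrast of 2: spectral hole burning with an 80 dB
filter images deepest (~4.7 cm), photorefractive and holographic detection
reach ~1.6-2.3 cm, and speckle contrast with a 1 Mpx camera is the
shallowest at ~0.9 cm.  The quoted errors are Monte-Carlo statistics of the
reference run; variant names encode the filter leak (30/80 dB), the
photorefractive grating efficiency (0.10/0.35) and the camera pixel count
(1/50 Mpx).

Other entry points, one narrative script per capability, live in
`examples/`: the detection-chain arithmetic (efficiencies, speckle counts,
photon budget, camera data rate), transport validation against diffusion
theory, and the speckle-contrast noise floor.  A thin CLI mirrors them:

```bash
uotcnr report
uotcnr transport --depth 1.0 --n-packets 100000 --seed 1 --out run
uotcnr depth-scan --contrast 2.0 --out results/ --plot
uotcnr speckle-noise --npx-side 256 --repeats 300 --seed 1
```

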
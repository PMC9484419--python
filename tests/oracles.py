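"""Independent Monte-Carlo measurement oracles for the closed-form CNR models.

Each oracle simulates the actual counting experiment a method performs and
computes the empirical CNR via the generic definition
|mean S_A - mean S_B| / sqrt(var S_A + var S_B).  They share no code with the
closed forms they check.
"""

from __future__ import annotations

import numpy as np


def empirical_cnr(samples_A: np.ndarray, samples_B: np.ndarray) -> float:
    sa = np.var(samples_A, ddof=1)
    sb = np.var(samples_B, ddof=1)
    return abs(np.mean(samples_A) - np.mean(samples_B)) / np.sqrt(sa + sb)


def shb_counting_oracle(
    N_T_A: float,
    N_T_B: float,
    N_U: float,
    S: float,
    eta_det: float,
    T_U: float,
    n_repeats: int,
    rng: np.random.Generator,
) -> float:
    """Poisson photon counting behind the two sideband filters.

    Each measurement counts both +/-1st-order tagged photons plus leaked
    untagged photons from the collected tissue area.
    """
    mean_A = S * eta_det * (2.0 * N_T_A + T_U * N_U)
    mean_B = S * eta_det * (2.0 * N_T_B + T_U * N_U)
    k_A = rng.poisson(mean_A, size=n_repeats)
    k_B = rng.poisson(mean_B, size=n_repeats)
    return empirical_cnr(k_A, k_B)


def photorefractive_counting_oracle(
    N_T_A: float,
    N_T_B: float,
    N_U: float,
    S: float,
    eta_det: float,
    eta_pr: float,
    n_repeats: int,
    rng: np.random.Generator,
    baseline_noisy: bool = False,
) -> float:
    """Ultrasound on/off subtraction on the photorefractive detector.

    The detector sits on the untagged background S eta (1+eta_pr)^2 N_U; the
    ultrasound adds 2 S eta eta_pr N_T.  The US-off baseline is taken as
    noiseless (averaged) unless ``baseline_noisy``.
    """
    background = S * eta_det * N_U * (1.0 + eta_pr) ** 2
    out = []
    for n_t in (N_T_A, N_T_B):
        on = rng.poisson(background + 2.0 * S * eta_det * eta_pr * n_t, size=n_repeats)
        off = rng.poisson(background, size=n_repeats) if baseline_noisy else background
        out.append(on - off)
    return empirical_cnr(out[0], out[1])


def _speckle_field(side: int, pupil_radius_bins: float, rng: np.random.Generator):
    fx = np.fft.fftfreq(side) * side
    FX, FY = np.meshgrid(fx, fx, indexing="ij")
    mask = FX * FX + FY * FY <= pupil_radius_bins**2
    pupil = np.zeros((side, side), dtype=complex)
    pupil[mask] = np.exp(1j * rng.uniform(0, 2 * np.pi, int(mask.sum())))
    field = np.fft.ifft2(pupil)
    return field / np.sqrt(np.mean(np.abs(field) ** 2))


def holography_pixel_oracle(
    nbar_eta_A: float,
    nbar_eta_B: float,
    n: int,
    side: int,
    mu_ref: float,
    n_repeats: int,
    rng: np.random.Generator,
) -> float:
    """Synthetic off-axis hologram with per-pixel Poisson statistics.

    ``nbar_eta_X`` is the detected tagged photon number per speckle (eta_det
    already applied); ``n`` pixels per speckle (speckle sqrt(n) px wide);
    ``mu_ref`` the per-pixel background count (reference plus untagged; the
    untagged light contributes only its shot noise here, matching the
    closed-form bookkeeping - its static self-interference speckle lobe is
    removed around DC in any real off-axis reconstruction).  Per repeat:
    build reference + tagged pixel means, draw Poisson counts, FFT, sum
    |F|^2 over the quarter plane around the carrier, subtract the shot-noise
    bias.  The empirical CNR of that energy estimator is returned.
    """
    speckle_px = np.sqrt(n)
    # carrier at a quarter of the sampling frequency on both axes
    k0 = side // 4
    x = np.arange(side)
    carrier = np.exp(1j * 2 * np.pi * k0 * (x[:, None] + x[None, :]) / side)
    pupil_radius = 1.61634 / (np.pi * speckle_px) * side
    t_per_px = {"A": nbar_eta_A / n, "B": nbar_eta_B / n}
    estimates = {"A": np.empty(n_repeats), "B": np.empty(n_repeats)}
    sl = slice(1, side // 2)
    n_crop = (side // 2 - 1) ** 2
    for key, t in t_per_px.items():
        for r in range(n_repeats):
            e_t = _speckle_field(side, pupil_radius, rng) * np.sqrt(t)
            mean = (
                mu_ref
                + np.abs(e_t) ** 2
                + 2.0 * np.sqrt(mu_ref) * (carrier * e_t).real
            )
            counts = rng.poisson(np.clip(mean, 0.0, None))
            F = np.fft.fft2(counts)
            energy = np.sum(np.abs(F[sl, sl]) ** 2)
            estimates[key][r] = energy - n_crop * counts.sum()
    return empirical_cnr(estimates["A"], estimates["B"])


def speckle_contrast_ensemble_oracle(
    ratio_A: float,
    ratio_B: float,
    side: int,
    n_repeats: int,
    rng: np.random.Generator,
    n_phases: int = 16,
) -> float:
    """Contrast measurements of modulated speckle ensembles, regions A vs B.

    ``ratio_X`` = N_T / N_U (+1st order).  Each measurement integrates the
    untagged field plus both sideband fields over uniform ultrasound phases
    and records std/mean of the intensity.
    """
    pupil_radius = 1.61634 / (np.pi * 2.0) * side  # 2 px speckles
    phases = np.exp(1j * 2 * np.pi * np.arange(n_phases) / n_phases)
    out = {}
    for key, ratio in (("A", ratio_A), ("B", ratio_B)):
        amp = np.sqrt(ratio)
        cs = np.empty(n_repeats)
        for r in range(n_repeats):
            e_u = _speckle_field(side, pupil_radius, rng)
            e_p = _speckle_field(side, pupil_radius, rng)
            e_m = _speckle_field(side, pupil_radius, rng)
            img = np.zeros((side, side))
            for ph in phases:
                img += np.abs(e_u + amp * (e_p * ph + e_m / ph)) ** 2
            cs[r] = np.std(img) / np.mean(img)
        out[key] = cs
    return empirical_cnr(out["A"], out["B"])
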
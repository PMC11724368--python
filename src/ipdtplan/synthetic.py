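"""Synthetic inputs with known ground truth.

Two generators feed the imaging side of the pipeline:

* ``gen_bimodal_tumor_map`` draws a disk tumor with a low-concentration
  core and a high-concentration rim on a narrow-range normal-tissue
  background, at the native 0.06 mm pixel pitch.  Default mode
  parameters (core mean 3.03, SD 1.25; rim mean 7.97, SD 3.37 ug/mL)
  reproduce the statistical structure of a strongly bimodal in vivo
  tumor; concentrations are zero-truncated for physical nonnegativity.

* ``gen_sfdi_frames`` forward-models structured-illumination
  acquisition: the concentration map is inverted through the
  diffusion-theory quantification formula to a fluorescence frame, and
  a three-phase reflectance triplet is synthesized whose demodulated
  amplitude equals the requested sample MAC, with optional additive
  noise applied last.  With zero noise, demodulation + quantification
  recovers the ground truth to numerical precision.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sfdi import Calibration, PhaseTriplet, PSMap, ReferenceSet, quantification_denominator

__all__ = ["GroundTruth", "gen_bimodal_tumor_map", "gen_sfdi_frames"]

#: Mode parameters (mean, SD) in ug/mL of the default bimodal tumor.
DEFAULT_CORE_MODE = (3.03, 1.25)
DEFAULT_RIM_MODE = (7.97, 3.37)
#: Normal-tissue background range (ug/mL): narrow, 0 to 0.9.
BACKGROUND_RANGE = (0.0, 0.9)


@dataclass(frozen=True)
class GroundTruth:
    ps_true: PSMap
    core_mode: tuple[float, float]
    rim_mode: tuple[float, float]
    noise_sd: float
    seed: int
    core_mask: np.ndarray | None = None
    rim_mask: np.ndarray | None = None


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Zero-truncated Gaussian by resampling (warns-by-exception budget
    handled by callers)."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    tries = 0
    while np.any(bad) and tries < 50:
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
        tries += 1
    return np.clip(out, 0.0, None)


def gen_bimodal_tumor_map(
    shape: tuple[int, int] = (128, 128),
    tumor_radius_px: int = 48,
    rim_fraction: float = 0.35,
    core_mode: tuple[float, float] = DEFAULT_CORE_MODE,
    rim_mode: tuple[float, float] = DEFAULT_RIM_MODE,
    pixel_pitch: float = 0.06,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PSMap, GroundTruth]:
    """Disk tumor with a core/rim annulus on a quiet background.

    ``rim_fraction`` is the fraction of the tumor radius occupied by the
    rim annulus.  Pixel values are drawn from the respective
    zero-truncated Gaussians; optional extra Gaussian noise of SD
    ``noise_sd`` is added afterwards (then re-clipped at zero).
    """
    if not (0.0 < rim_fraction < 1.0):
        raise ValueError("rim_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    tumor = r <= tumor_radius_px
    core = r <= tumor_radius_px * (1.0 - rim_fraction)
    rim = tumor & ~core

    for name, (mean, sd) in (("core", core_mode), ("rim", rim_mode)):
        if mean <= 0:
            raise ValueError(f"{name} mode mean must be positive")
        # warn (softly) if truncation is severe
        from scipy.stats import norm

        if norm.cdf(0.0, loc=mean, scale=sd) > 0.10:
            import warnings

            warnings.warn(
                f"{name} mode truncates more than 10% of its mass at zero"
            )

    ps = np.empty(shape)
    lo, hi = BACKGROUND_RANGE
    bg_mean, bg_sd = 0.5 * (lo + hi), (hi - lo) / 6.0
    ps[~tumor] = _truncated_normal(rng, bg_mean, bg_sd, int((~tumor).sum()))
    ps[core] = _truncated_normal(rng, core_mode[0], core_mode[1], int(core.sum()))
    ps[rim] = _truncated_normal(rng, rim_mode[0], rim_mode[1], int(rim.sum()))
    if noise_sd > 0:
        ps = np.clip(ps + rng.normal(0.0, noise_sd, shape), 0.0, None)

    ps_map = PSMap(ps=ps, pixel_pitch=pixel_pitch, mask=tumor)
    truth = GroundTruth(
        ps_true=ps_map,
        core_mode=core_mode,
        rim_mode=rim_mode,
        noise_sd=noise_sd,
        seed=seed,
        core_mask=core,
        rim_mask=rim,
    )
    return ps_map, truth


def gen_sfdi_frames(
    ps_true: PSMap,
    refs: ReferenceSet,
    cal: Calibration,
    modulation: tuple[float, float, float] = (1000.0, 300.0, 0.0),
    spatial_frequency: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PhaseTriplet, np.ndarray]:
    """Forward-model a reflectance phase triplet and fluorescence frame.

    ``modulation`` = (DC, amplitude, phase): the reflectance frames are
    DC + A*cos(phase + k*120deg) so the demodulated sample MAC equals A
    everywhere.  The fluorescence frame Fm solves the quantification
    formula for the given ground-truth concentrations with these
    references and calibration.  Additive Gaussian noise of SD
    ``noise_sd`` (detector units on the triplet, relative units on Fm)
    is applied last, clipped at zero.
    """
    refs.validate()
    cal.validate()
    dc, amp, phase = modulation
    if dc <= 0 or amp < 0 or amp > dc:
        raise ValueError("modulation requires 0 <= amplitude <= DC, DC > 0")
    rng = np.random.default_rng(seed)
    shape = ps_true.ps.shape

    mac_sample = np.full(shape, float(amp))
    denom = quantification_denominator(mac_sample, refs)
    fm = ps_true.ps * denom / (cal.k_ps * cal.mu_a_x)

    frames = []
    for k in range(3):
        frame = dc + amp * np.cos(phase + k * 2.0 * np.pi / 3.0) * np.ones(shape)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, shape)
        frames.append(np.clip(frame, 0.0, None))
    if noise_sd > 0:
        fm = np.clip(fm + rng.normal(0.0, noise_sd / dc * np.maximum(fm, 1e-12), shape), 0.0, None)
    triplet = PhaseTriplet(
        i1=frames[0],
        i2=frames[1],
        i3=frames[2],
        spatial_frequency=spatial_frequency,
        pixel_pitch=ps_true.pixel_pitch,
        wavelength_role="excitation",
    )
    return triplet, fm
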
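"""Quantitative spatial-frequency-domain imaging (qSFDI).

Three sinusoidal illumination patterns with a 120-degree phase shift are
projected onto the sample; demodulating the three frames yields the
modulation amplitude of the structured reflectance (MAC) at each pixel.
Referencing the sample MAC against a phantom of known optical properties,
together with the demodulated fluorescence emission, gives a quantitative
photosensitizer concentration map in ug/mL via a diffusion-theory
correction for the optical properties of the tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseTriplet",
    "ModulationImage",
    "ReferenceSet",
    "Calibration",
    "PSMap",
    "demodulate",
    "quantify_ps",
    "quantification_denominator",
    "detection_limit",
]

#: Prefactor of three-phase amplitude demodulation. For frames
#: I_k = DC + A*cos(phi + k*120deg) the root-sum-of-squared-differences
#: equals 3*A/sqrt(2), so sqrt(2)/3 recovers the amplitude A exactly.
DEMOD_PREFACTOR = np.sqrt(2.0) / 3.0


@dataclass(frozen=True)
class PhaseTriplet:
    """Three co-registered intensity frames at one spatial frequency.

    Frames are in arbitrary detector units; ``spatial_frequency`` in 1/mm
    (the acquisition set is {0, 0.2, 0.5} 1/mm, with 0.5 the analysis
    default), ``pixel_pitch`` in mm (square pixels).
    """

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    spatial_frequency: float
    pixel_pitch: float = 0.06
    wavelength_role: Literal["excitation", "emission"] = "excitation"

    def __post_init__(self) -> None:
        i1 = np.asarray(self.i1, dtype=float)
        i2 = np.asarray(self.i2, dtype=float)
        i3 = np.asarray(self.i3, dtype=float)
        if not (i1.shape == i2.shape == i3.shape):
            raise ValueError(
                f"phase frames must share shape, got {i1.shape}, {i2.shape}, {i3.shape}"
            )
        for name, frame in (("i1", i1), ("i2", i2), ("i3", i3)):
            if np.any(frame < 0):
                raise ValueError(f"negative intensities in frame {name}")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "i1", i1)
        object.__setattr__(self, "i2", i2)
        object.__setattr__(self, "i3", i3)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.i1.shape


@dataclass(frozen=True)
class ModulationImage:
    """Demodulated modulation amplitude (MAC), same units as the frames."""

    mac: np.ndarray
    spatial_frequency: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mac", np.asarray(self.mac, dtype=float))


@dataclass(frozen=True)
class ReferenceSet:
    """Reference-phantom quantities entering the quantification formula.

    ``mac_ref`` is the modulation amplitude of the reference phantom,
    ``rx_ref``/``rm_ref`` the phantom diffuse reflectances at the
    excitation and emission wavelengths.  Scalars broadcast over the map.
    """

    mac_ref: np.ndarray | float
    rx_ref: np.ndarray | float
    rm_ref: np.ndarray | float

    def validate(self) -> None:
        for name in ("mac_ref", "rx_ref", "rm_ref"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Calibration:
    """Concentration calibration: k_ps maps corrected fluorescence to
    ug/mL; mu_a_x is the tissue absorption coefficient at the excitation
    wavelength in 1/mm."""

    k_ps: float
    mu_a_x: float

    def validate(self) -> None:
        if self.k_ps <= 0:
            raise ValueError("k_ps must be positive")
        if self.mu_a_x <= 0:
            raise ValueError("mu_a_x must be positive")


@dataclass
class PSMap:
    """Photosensitizer concentration image in ug/mL.

    ``mask`` optionally restricts the region of interest; ``invalid``
    marks pixels where quantification failed (nonpositive denominator).
    """

    ps: np.ndarray
    pixel_pitch: float = 0.06
    mask: np.ndarray | None = None
    invalid: np.ndarray | None = None
    n_clamped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ps = np.asarray(self.ps, dtype=float)
        if self.mask is not None and self.mask.shape != self.ps.shape:
            raise ValueError("mask shape must match ps map shape")

    def roi_values(self) -> np.ndarray:
        """Flat array of in-ROI, valid pixel values."""
        keep = np.ones(self.ps.shape, dtype=bool)
        if self.mask is not None:
            keep &= self.mask.astype(bool)
        if self.invalid is not None:
            keep &= ~self.invalid
        return self.ps[keep]


def demodulate(triplet: PhaseTriplet) -> ModulationImage:
    """Recover the modulation amplitude from three 120-deg phase frames.

    MAC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2),
    which returns exactly the sinusoid amplitude A for ideal frames
    I_k = DC + A*cos(phi + k*120deg), independent of DC and phi.
    """
    i1, i2, i3 = triplet.i1, triplet.i2, triplet.i3
    mac = DEMOD_PREFACTOR * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    return ModulationImage(mac=mac, spatial_frequency=triplet.spatial_frequency)


def quantification_denominator(
    mac_sample: np.ndarray, refs: ReferenceSet
) -> np.ndarray:
    """Diffusion-theory denominator of the concentration formula.

    D = 1 - (1 - (MACs/MACref)*Rx_ref) * (MACs/MACref)*Rm_ref

    Exposed separately so the grouping can be inspected and A/B-tested
    against alternate readings of the formula.
    """
    ratio = np.asarray(mac_sample, dtype=float) / np.asarray(refs.mac_ref, dtype=float)
    return 1.0 - (1.0 - ratio * np.asarray(refs.rx_ref)) * ratio * np.asarray(
        refs.rm_ref
    )


def quantify_ps(
    fm: np.ndarray | ModulationImage,
    mac_sample: ModulationImage,
    refs: ReferenceSet,
    cal: Calibration,
    *,
    pixel_pitch: float = 0.06,
    denom_epsilon: float = 1e-9,
    max_invalid_fraction: float = 0.25,
) -> PSMap:
    """Convert fluorescence and reflectance modulation into [PS] (ug/mL).

    [PS] = k_ps * mu_a_x * Fm / D with D the diffusion-theory
    denominator.  ``fm`` may be a raw fluorescence frame or a demodulated
    fluorescence modulation image (both are accepted; raw frame is the
    default acquisition mode).

    Pixels with D <= ``denom_epsilon`` are flagged invalid rather than
    silently zeroed; if their fraction exceeds ``max_invalid_fraction``
    a ValueError reports the count.  Negative concentrations (possible
    with noisy Fm) are clamped to zero and counted.
    """
    refs.validate()
    cal.validate()
    fm_arr = fm.mac if isinstance(fm, ModulationImage) else np.asarray(fm, dtype=float)
    if fm_arr.shape != mac_sample.mac.shape:
        raise ValueError("fm and mac_sample shapes differ")

    denom = quantification_denominator(mac_sample.mac, refs)
    invalid = denom <= denom_epsilon
    n_invalid = int(invalid.sum())
    if n_invalid > max_invalid_fraction * denom.size:
        raise ValueError(
            f"quantification denominator nonpositive at {n_invalid} pixels "
            f"({n_invalid / denom.size:.1%} of map)"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        ps = cal.k_ps * cal.mu_a_x * fm_arr / denom
    ps[invalid] = 0.0
    negative = ps < 0
    n_clamped = int(negative.sum())
    ps[negative] = 0.0
    if n_invalid or n_clamped:
        logger.info(
            "quantify_ps: %d invalid-denominator pixels, %d negatives clamped",
            n_invalid,
            n_clamped,
        )
    return PSMap(
        ps=ps,
        pixel_pitch=pixel_pitch,
        invalid=invalid if n_invalid else None,
        n_clamped=n_clamped,
        meta={"n_invalid": n_invalid},
    )


def detection_limit(
    dilution_series: Sequence[tuple[float, PSMap]],
) -> float | None:
    """Lowest concentration distinguishable from blank (3-sigma rule).

    ``dilution_series`` pairs true concentrations with recovered maps and
    must include a zero-concentration blank.  Returns the smallest true
    concentration whose mean recovered signal exceeds
    mean(blank) + 3*SD(blank), or ``None`` if no dilution passes.
    """
    blanks = [m for c, m in dilution_series if c == 0.0]
    if not blanks:
        raise ValueError("dilution series must include a zero-concentration blank")
    blank_vals = np.concatenate([m.roi_values() for m in blanks])
    criterion = blank_vals.mean() + 3.0 * blank_vals.std(ddof=1 if blank_vals.size > 1 else 0)
    passing = [
        c
        for c, m in dilution_series
        if c > 0 and m.roi_values().mean() > criterion
    ]
    return min(passing) if passing else None
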
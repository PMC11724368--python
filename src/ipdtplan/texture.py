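"""Sliding-window gray-level co-occurrence (GLCM) texture analysis.

Concentration maps are quantized to a fixed number of gray levels over a
study-wide dynamic range, and three Haralick features are computed in a
sliding window (step 1) from the symmetric, normalized co-occurrence
matrix at unit pixel distance:

    contrast    = sum_ij (i-j)^2 p(i,j)
    energy      = sum_ij p(i,j)^2
    homogeneity = sum_ij p(i,j) / (1 + |i-j|)

Features are averaged over the four principal offset angles
(0, 45, 90, 135 degrees).  The homogeneity kernel is the inverse-
difference variant 1/(1+|i-j|); the inverse-difference-moment variant
1/(1+(i-j)^2) is available via ``homogeneity_kernel="idm"`` since both
circulate under the same name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from skimage.feature import graycomatrix

from .sfdi import PSMap

__all__ = [
    "QuantizationSpec",
    "GlcmMatrix",
    "TextureMap",
    "quantize",
    "glcm",
    "haralick",
    "sliding_texture",
    "texture_summary",
]

ANGLES_DEG = (0, 45, 90, 135)
# pixel offsets (drow, dcol) per angle at distance 1, following skimage's
# convention (row = r + sin(angle), col = c + cos(angle)); for symmetric
# GLCMs an offset and its negation are equivalent.
_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


@dataclass(frozen=True)
class QuantizationSpec:
    """Gray-level quantization held constant across a study.

    ``dynamic_range`` (lo, hi) in ug/mL is taken from the study-wide
    histogram; values outside are clipped."""

    n_levels: int = 32
    dynamic_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        lo, hi = self.dynamic_range
        if lo >= hi:
            raise ValueError("dynamic_range must satisfy lo < hi")


@dataclass(frozen=True)
class GlcmMatrix:
    """Normalized co-occurrence matrix at one offset."""

    p: np.ndarray
    angle_deg: int
    distance: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        object.__setattr__(self, "p", p)


@dataclass
class TextureMap:
    """Per-pixel feature maps for one window size (features averaged over
    the four angles; maps cover pixels where the full window fits)."""

    contrast: np.ndarray
    energy: np.ndarray
    homogeneity: np.ndarray
    window_size: int
    step: int = 1


def quantize(ps_map: PSMap | np.ndarray, spec: QuantizationSpec) -> np.ndarray:
    """Quantize concentrations into integer levels [0, n_levels).

    Equal-width bins over the dynamic range; out-of-range values clip to
    the extreme levels, and hi itself maps to the top level."""
    values = ps_map.ps if isinstance(ps_map, PSMap) else np.asarray(ps_map, dtype=float)
    lo, hi = spec.dynamic_range
    scaled = (values - lo) / (hi - lo) * spec.n_levels
    levels = np.clip(np.floor(scaled), 0, spec.n_levels - 1)
    return levels.astype(np.int64)


def glcm(
    window: np.ndarray,
    angle_deg: int = 0,
    *,
    n_levels: int | None = None,
    symmetric: bool = True,
    normalize: bool = True,
) -> GlcmMatrix:
    """Co-occurrence matrix of a level image at unit distance.

    Counts pairs of levels at the angle's pixel offset, optionally
    symmetrized (adding the transpose) and normalized to sum 1.
    """
    window = np.asarray(window)
    if window.ndim != 2 or min(window.shape) < 2:
        raise ValueError("window must be at least 2x2")
    if angle_deg not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    levels = int(n_levels) if n_levels is not None else int(window.max()) + 1
    # skimage's angle convention matches ours: angle measured so that
    # 45deg pairs (r, c) with (r-1, c+1).
    p = graycomatrix(
        window.astype(np.uint8),
        distances=[1],
        angles=[np.deg2rad(angle_deg)],
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )[:, :, 0, 0].astype(float)
    if p.sum() == 0:
        raise ValueError("window smaller than offset reach: no pixel pairs")
    if normalize:
        p = p / p.sum()
    return GlcmMatrix(p=p, angle_deg=angle_deg, symmetric=symmetric)


def haralick(
    m: GlcmMatrix, *, homogeneity_kernel: str = "inverse_difference"
) -> tuple[float, float, float]:
    """(contrast, energy, homogeneity) of a normalized GLCM."""
    p = m.p
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("haralick features require a normalized GLCM")
    i, j = np.indices(p.shape)
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p**2))
    if homogeneity_kernel == "inverse_difference":
        homog = float(np.sum(p / (1.0 + np.abs(i - j))))
    elif homogeneity_kernel == "idm":
        homog = float(np.sum(p / (1.0 + (i - j) ** 2)))
    else:
        raise ValueError(f"unknown homogeneity kernel {homogeneity_kernel!r}")
    return contrast, energy, homog


@njit(cache=True)
def _sliding_features(levels, n_levels, w, offsets, idm):  # pragma: no cover
    h, wid = levels.shape
    oh, ow = h - w + 1, wid - w + 1
    n_angles = offsets.shape[0]
    contrast = np.zeros((oh, ow))
    energy = np.zeros((oh, ow))
    homog = np.zeros((oh, ow))
    counts = np.zeros((n_levels, n_levels))
    for r0 in range(oh):
        for c0 in range(ow):
            csum, esum, hsum = 0.0, 0.0, 0.0
            for a in range(n_angles):
                dr, dc = offsets[a, 0], offsets[a, 1]
                counts[:, :] = 0.0
                npairs = 0.0
                for r in range(r0, r0 + w):
                    rr = r + dr
                    if rr < r0 or rr >= r0 + w:
                        continue
                    for c in range(c0, c0 + w):
                        cc = c + dc
                        if cc < c0 or cc >= c0 + w:
                            continue
                        li = levels[r, c]
                        lj = levels[rr, cc]
                        counts[li, lj] += 1.0
                        counts[lj, li] += 1.0  # symmetric
                        npairs += 2.0
                if npairs == 0.0:
                    continue
                con, ene, hom = 0.0, 0.0, 0.0
                for li in range(n_levels):
                    for lj in range(n_levels):
                        p = counts[li, lj] / npairs
                        if p == 0.0:
                            continue
                        d = li - lj
                        con += d * d * p
                        ene += p * p
                        if idm:
                            hom += p / (1.0 + d * d)
                        else:
                            hom += p / (1.0 + abs(d))
                csum += con
                esum += ene
                hsum += hom
            contrast[r0, c0] = csum / n_angles
            energy[r0, c0] = esum / n_angles
            homog[r0, c0] = hsum / n_angles
    return contrast, energy, homog


def sliding_texture(
    ps_map: PSMap | np.ndarray,
    spec: QuantizationSpec,
    window_sizes: Sequence[int] = (3, 5, 15, 20),
    angles_deg: Sequence[int] = ANGLES_DEG,
    *,
    homogeneity_kernel: str = "inverse_difference",
) -> dict[int, TextureMap]:
    """Per-pixel Haralick features at several window sizes.

    The window slides with step 1; features are computed only where the
    full window fits (no padding) and averaged over the requested
    angles.  Window size 1 is not meaningful (a single pixel has no
    pairs); the smallest supported window is 3.
    """
    levels = quantize(ps_map, spec)
    h, w_img = levels.shape
    feasible = [w for w in window_sizes if 3 <= w <= min(h, w_img)]
    if len(feasible) != len(list(window_sizes)):
        bad = sorted(set(window_sizes) - set(feasible))
        raise ValueError(
            f"window sizes {bad} infeasible for a {h}x{w_img} image; "
            f"feasible sizes are 3..{min(h, w_img)}"
        )
    offsets = np.array([_OFFSETS[a] for a in angles_deg], dtype=np.int64)
    out: dict[int, TextureMap] = {}
    for w in feasible:
        con, ene, hom = _sliding_features(
            levels, spec.n_levels, w, offsets, homogeneity_kernel == "idm"
        )
        out[w] = TextureMap(contrast=con, energy=ene, homogeneity=hom, window_size=w)
    return out


def texture_summary(maps: dict[int, TextureMap]) -> "pandas.DataFrame":
    """Box/whisker summary per window size (median, quartiles, whiskers
    at 1.5 IQR clipped to the data) for each feature."""
    import pandas as pd

    rows = []
    for w, tm in sorted(maps.items()):
        for name in ("contrast", "energy", "homogeneity"):
            v = np.ravel(getattr(tm, name))
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo = v[v >= q1 - 1.5 * iqr].min() if v.size else np.nan
            hi = v[v <= q3 + 1.5 * iqr].max() if v.size else np.nan
            rows.append(
                {
                    "window_size": w,
                    "feature": name,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_lo": lo,
                    "whisker_hi": hi,
                    "mean": v.mean(),
                }
            )
    return pd.DataFrame(rows)
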
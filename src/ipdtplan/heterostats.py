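"""Photosensitizer-distribution statistics inside a region of interest.

Tumor [PS] histograms are typically bimodal: a low-concentration mode in
the poorly perfused core and a high-concentration mode in the
well-perfused rim.  This module builds ROI histograms, separates the
modes with Otsu's histogram threshold, fits a two-component Gaussian
mixture, and reports the summary statistics used to characterize
intra-tumor heterogeneity (per-mode coefficient of variation, the
10th-90th percentile range, the fold range of mode means, and the
dimensionless mode separation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .sfdi import PSMap

__all__ = [
    "RoiHistogram",
    "OtsuResult",
    "BimodalFit",
    "HeterogeneitySummary",
    "build_histogram",
    "otsu_threshold",
    "fit_bimodal",
    "fit_bimodal_density",
    "summarize",
    "round_half_up",
]


@dataclass(frozen=True)
class RoiHistogram:
    """Histogram of ROI concentrations (bin edges in ug/mL)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if len(counts) != len(edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if counts.sum() != self.n_total:
            raise ValueError("histogram counts must conserve the ROI pixel count")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class OtsuResult:
    threshold: float
    between_class_variance: float
    foreground: np.ndarray | None = None


@dataclass(frozen=True)
class BimodalFit:
    """Two-component Gaussian mixture, components ordered by mean."""

    weight_1: float
    mean_1: float
    sd_1: float
    weight_2: float
    mean_2: float
    sd_2: float
    converged: bool
    log_likelihood: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mean_1 > self.mean_2:
            raise ValueError("components must be ordered by mean")


@dataclass(frozen=True)
class HeterogeneitySummary:
    cv_mode1: float | None
    cv_mode2: float | None
    iqr_10_90: float
    fold_range_mode2: float | None
    bimodal_separation: float


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the reporting convention here),
    unlike numpy's banker's rounding."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def build_histogram(
    ps_map: PSMap | np.ndarray,
    roi: np.ndarray | None = None,
    bins: int | Sequence[float] = 256,
) -> RoiHistogram:
    """Histogram the in-ROI concentrations.

    ``bins`` follows numpy semantics (count over the data range, or
    explicit monotone edges).
    """
    if isinstance(ps_map, PSMap):
        values = ps_map.ps
        if roi is None:
            roi = ps_map.mask
    else:
        values = np.asarray(ps_map, dtype=float)
    if roi is not None:
        values = values[np.asarray(roi, dtype=bool)]
    values = np.ravel(values)
    if values.size == 0:
        raise ValueError("empty ROI")
    counts, edges = np.histogram(values, bins=bins)
    # numpy drops out-of-range values for explicit edges; conserve them
    # by clipping into the outer bins so counts always sum to the ROI size.
    if counts.sum() != values.size:
        clipped = np.clip(values, edges[0], edges[-1])
        counts, edges = np.histogram(clipped, bins=edges)
    return RoiHistogram(bin_edges=edges, counts=counts, n_total=values.size)


def otsu_threshold(hist: RoiHistogram) -> OtsuResult:
    """Otsu's threshold computed from histogram counts.

    Scans every cut between bins and returns the bin edge maximizing the
    between-class variance w0*w1*(mu0-mu1)^2; ties break toward the
    lower edge.
    """
    counts = hist.counts.astype(float)
    if np.count_nonzero(counts) < 2:
        raise ValueError("Otsu threshold needs at least two nonempty bins")
    centers = hist.centers
    total = counts.sum()
    p = counts / total
    omega0 = np.cumsum(p)[:-1]  # cut after bin k, k = 0..nbins-2
    omega1 = 1.0 - omega0
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum[:-1] / omega0
        mu1 = (mu_total - mu_cum[:-1]) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximum
    return OtsuResult(
        threshold=float(hist.bin_edges[k + 1]),
        between_class_variance=float(sigma_b[k]),
    )


def fit_bimodal(
    values: np.ndarray,
    *,
    seed: int = 0,
    min_n: int = 50,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> BimodalFit:
    """Fit a two-component Gaussian mixture by EM.

    Components are returned ordered by mean.  A fit whose means lie
    within one pooled SD of each other is flagged degenerate (no second
    mode found); non-convergence is flagged but parameters are still
    returned.
    """
    values = np.ravel(np.asarray(values, dtype=float))
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {values.size}")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        n_init=5,
        init_params="k-means++",
        random_state=seed,
    )
    gm.fit(values[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    pooled_sd = float(np.sqrt(weights @ (sds**2)))
    # no second mode: either the means collapse within one pooled SD or a
    # single Gaussian explains the sample at least as well (BIC)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(values[:, None])
    degenerate = bool(
        means[1] - means[0] < pooled_sd
        or gm1.bic(values[:, None]) <= gm.bic(values[:, None])
    )
    return BimodalFit(
        weight_1=float(weights[0]),
        mean_1=float(means[0]),
        sd_1=float(sds[0]),
        weight_2=float(weights[1]),
        mean_2=float(means[1]),
        sd_2=float(sds[1]),
        converged=bool(gm.converged_),
        log_likelihood=float(gm.score(values[:, None]) * values.size),
        degenerate=degenerate,
    )


def fit_bimodal_density(
    hist: RoiHistogram, *, seed: int = 0
) -> BimodalFit:
    """Alternate fit: least squares of a two-Gaussian density against the
    normalized histogram (the mixture-of-normals overlay drawn on density
    plots)."""
    from scipy.optimize import curve_fit

    centers = hist.centers
    widths = np.diff(hist.bin_edges)
    density = hist.counts / (hist.n_total * widths)

    def model(x, w1, m1, s1, m2, s2):
        g1 = np.exp(-0.5 * ((x - m1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
        g2 = np.exp(-0.5 * ((x - m2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
        return w1 * g1 + (1 - w1) * g2

    rng = np.random.default_rng(seed)
    lo, hi = centers[0], centers[-1]
    span = hi - lo
    p0 = [
        0.5,
        lo + 0.25 * span + 0.01 * span * rng.standard_normal(),
        0.15 * span,
        lo + 0.75 * span + 0.01 * span * rng.standard_normal(),
        0.15 * span,
    ]
    bounds = ([0, lo - span, 1e-6, lo - span, 1e-6], [1, hi + span, span * 2, hi + span, span * 2])
    try:
        popt, _ = curve_fit(model, centers, density, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    w1, m1, s1, m2, s2 = popt
    if m1 > m2:
        m1, s1, m2, s2 = m2, s2, m1, s1
        w1 = 1 - w1
    resid = float(np.sum((model(centers, *popt) - density) ** 2))
    pooled = float(np.sqrt(w1 * s1**2 + (1 - w1) * s2**2))
    return BimodalFit(
        weight_1=float(w1),
        mean_1=float(m1),
        sd_1=float(s1),
        weight_2=float(1 - w1),
        mean_2=float(m2),
        sd_2=float(s2),
        converged=converged,
        log_likelihood=-resid,
        degenerate=bool(m2 - m1 < pooled),
    )


def summarize(
    values: np.ndarray,
    fit: BimodalFit,
    per_slice_mode2_means: Sequence[float] | None = None,
) -> HeterogeneitySummary:
    """Heterogeneity summary: per-mode CV = sd/mean, 10-90 percentile
    range of the pooled sample, fold range max/min of per-slice mode-2
    means, and the mode separation (mean_2-mean_1)/pooled SD."""
    values = np.ravel(np.asarray(values, dtype=float))
    cv1 = fit.sd_1 / fit.mean_1 if fit.mean_1 > 0 else None
    cv2 = fit.sd_2 / fit.mean_2 if fit.mean_2 > 0 else None
    p10, p90 = np.percentile(values, [10, 90])  # linear interpolation
    fold = None
    if per_slice_mode2_means is not None:
        m = np.asarray(per_slice_mode2_means, dtype=float)
        if m.size and m.min() > 0:
            fold = float(m.max() / m.min())
    pooled_sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    separation = (
        (fit.mean_2 - fit.mean_1) / pooled_sd if pooled_sd > 0 else 0.0
    )
    return HeterogeneitySummary(
        cv_mode1=cv1,
        cv_mode2=cv2,
        iqr_10_90=float(p90 - p10),
        fold_range_mode2=fold,
        bimodal_separation=float(separation),
    )
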
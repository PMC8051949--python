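"""Axial two-Gaussian decomposition of nuclear-envelope staining profiles.

An apical→basal intensity profile through a nucleus shows two peaks — one per
side of the nuclear envelope.  Each profile is fit to a constant baseline
plus two Gaussians; the basal/apical ratio of the Gaussian areas is the
per-nucleus asymmetry statistic, and ratios are summarised as fixed-width
histograms per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import UnresolvedProfileError

logger = logging.getLogger(__name__)

__all__ = [
    "ZProfile",
    "TwoGaussianFit",
    "RatioHistogram",
    "extract_z_profile",
    "fit_two_gaussians",
    "basal_apical_ratio",
    "bin_ratios",
]

MIN_SAMPLES = 15


@dataclass
class ZProfile:
    """Axial intensity profile, apical first.

    ``positions`` must be strictly increasing; at least 15 samples are
    required for a two-Gaussian fit to be meaningful.
    """

    positions: np.ndarray
    intensities: np.ndarray
    nucleus_id: str = ""
    compartment: str = "unknown"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be matching 1-D arrays")
        if len(self.positions) < MIN_SAMPLES:
            raise ValueError(
                f"profile has {len(self.positions)} samples; >= {MIN_SAMPLES} required"
            )
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.compartment not in ("periphery", "interior", "unknown"):
            raise ValueError(f"bad compartment: {self.compartment!r}")


@dataclass
class TwoGaussianFit:
    """Baseline + two-Gaussian decomposition of a :class:`ZProfile`.

    Peaks are ordered so the apical component has the smaller position.
    AUCs use the analytic Gaussian integral amp * sigma * sqrt(2*pi).
    """

    baseline: float
    apical_amp: float
    apical_mu: float
    apical_sigma: float
    basal_amp: float
    basal_mu: float
    basal_sigma: float
    rss: float
    converged: bool
    nucleus_id: str = ""
    compartment: str = "unknown"

    @property
    def auc_apical(self) -> float:
        return self.apical_amp * self.apical_sigma * np.sqrt(2 * np.pi)

    @property
    def auc_basal(self) -> float:
        return self.basal_amp * self.basal_sigma * np.sqrt(2 * np.pi)

    @property
    def ratio(self) -> float:
        return basal_apical_ratio(self)


@dataclass
class RatioHistogram:
    """Fixed-width histogram of ratios, expressed as percentages per group."""

    bin_width: float
    bin_centers: np.ndarray
    percentages: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, pct in self.percentages.items():
            for c, p in zip(self.bin_centers, pct):
                rows.append({"bin_center": c, "group": group, "percentage": p})
        return pd.DataFrame(rows)


def two_gaussian_model(z, baseline, a1, mu1, s1, a2, mu2, s2):
    return (
        baseline
        + a1 * np.exp(-((z - mu1) ** 2) / (2 * s1**2))
        + a2 * np.exp(-((z - mu2) ** 2) / (2 * s2**2))
    )


def extract_z_profile(
    zstack: np.ndarray,
    line_endpoints: tuple[tuple[float, float], tuple[float, float]],
    averaging_halfwidth: float = 0.0,
    z_spacing: float = 1.0,
    nucleus_id: str = "",
    compartment: str = "unknown",
) -> ZProfile:
    """Average a z-stack over a line footprint to get one axial profile.

    ``zstack`` is (z, y, x); ``line_endpoints`` are two (x, y) pixel
    coordinates.  Per z-slice, the intensity is the mean over pixels whose
    centre lies within ``averaging_halfwidth`` of the segment (halfwidth 0
    selects the rasterised line itself).
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3:
        raise ValueError("zstack must be 3-D (z, y, x)")
    nz, ny, nx = zstack.shape
    if nz < MIN_SAMPLES:
        raise ValueError(f"stack has {nz} slices; >= {MIN_SAMPLES} required")
    (x0, y0), (x1, y1) = line_endpoints
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(f"line endpoint ({x}, {y}) outside image footprint")

    yy, xx = np.mgrid[0:ny, 0:nx]
    dx, dy = x1 - x0, y1 - y0
    seg_len2 = dx * dx + dy * dy
    if seg_len2 == 0:
        dist = np.hypot(xx - x0, yy - y0)
    else:
        t = ((xx - x0) * dx + (yy - y0) * dy) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
    footprint = dist <= max(averaging_halfwidth, 0.5 if averaging_halfwidth == 0 else 0)
    if averaging_halfwidth == 0:
        # rasterised line: nearest-pixel footprint along the segment
        n_steps = int(max(abs(dx), abs(dy))) + 1
        fp = np.zeros((ny, nx), dtype=bool)
        for t in np.linspace(0.0, 1.0, n_steps):
            fp[int(round(y0 + t * dy)), int(round(x0 + t * dx))] = True
        footprint = fp
    intensities = zstack[:, footprint].mean(axis=1)
    positions = np.arange(nz) * z_spacing
    return ZProfile(positions, intensities, nucleus_id=nucleus_id, compartment=compartment)


def _initial_guess(z: np.ndarray, y: np.ndarray) -> tuple[float, ...]:
    """Moving-average smoothing + peak finding for fit initialisation."""
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="same")
    baseline = float(smooth.min())
    peaks, props = find_peaks(smooth, prominence=0.05 * (smooth.max() - baseline + 1e-12))
    if len(peaks) < 2:
        raise UnresolvedProfileError(
            "fewer than two detectable peaks in profile; cannot resolve "
            "apical and basal envelope"
        )
    order = np.argsort(props["prominences"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    spacing = float(np.median(np.diff(z)))

    def fwhm_sigma(idx):
        half = baseline + (smooth[idx] - baseline) / 2.0
        left = idx
        while left > 0 and smooth[left] > half:
            left -= 1
        right = idx
        while right < len(z) - 1 and smooth[right] > half:
            right += 1
        width = z[right] - z[left]
        return max(width / 2.355, spacing)

    return (
        baseline,
        float(smooth[p1] - baseline),
        float(z[p1]),
        fwhm_sigma(p1),
        float(smooth[p2] - baseline),
        float(z[p2]),
        fwhm_sigma(p2),
    )


def fit_two_gaussians(profile: ZProfile, max_restarts: int = 3) -> TwoGaussianFit:
    """Nonlinear least-squares fit of baseline + two Gaussians.

    Raises :class:`UnresolvedProfileError` when fewer than two peaks are
    detectable, or when the fitted peaks are closer than the wider fitted
    sigma (overlapping envelope sides cannot be apportioned).
    """
    z, y = profile.positions, profile.intensities
    p0 = _initial_guess(z, y)
    span = z[-1] - z[0]
    spacing = float(np.median(np.diff(z)))
    ymax = float(y.max())
    lower = [0.0, 0.0, z[0], spacing, 0.0, z[0], spacing]
    upper = [ymax, 2 * ymax, z[-1], span / 2, 2 * ymax, z[-1], span / 2]
    p0 = tuple(np.clip(p0, lower, upper))

    rng = np.random.default_rng(0)
    popt, converged = None, False
    for attempt in range(max_restarts + 1):
        guess = np.asarray(p0, dtype=float)
        if attempt > 0:
            guess = guess * (1 + 0.1 * rng.standard_normal(len(guess)))
            guess = np.clip(guess, lower, upper)
        try:
            popt, _ = curve_fit(
                two_gaussian_model, z, y, p0=guess, bounds=(lower, upper), maxfev=20000
            )
            converged = True
            break
        except RuntimeError:
            continue
    if popt is None:
        popt = np.asarray(p0, dtype=float)
        logger.warning("two-Gaussian fit did not converge for %r", profile.nucleus_id)

    baseline, a1, mu1, s1, a2, mu2, s2 = (float(v) for v in popt)
    if mu1 > mu2:
        a1, mu1, s1, a2, mu2, s2 = a2, mu2, s2, a1, mu1, s1
    if converged and abs(mu2 - mu1) < max(s1, s2):
        raise UnresolvedProfileError(
            f"fitted peaks at {mu1:.3g} and {mu2:.3g} closer than max sigma "
            f"{max(s1, s2):.3g}; profile unresolved"
        )
    resid = y - two_gaussian_model(z, baseline, a1, mu1, s1, a2, mu2, s2)
    return TwoGaussianFit(
        baseline=baseline,
        apical_amp=a1,
        apical_mu=mu1,
        apical_sigma=s1,
        basal_amp=a2,
        basal_mu=mu2,
        basal_sigma=s2,
        rss=float(resid @ resid),
        converged=converged,
        nucleus_id=profile.nucleus_id,
        compartment=profile.compartment,
    )


def basal_apical_ratio(fit: TwoGaussianFit) -> float:
    """Area ratio basal/apical; the sqrt(2*pi) factors cancel."""
    if not fit.converged:
        raise ValueError("ratio requested from a non-converged fit")
    denom = fit.apical_amp * fit.apical_sigma
    if denom == 0:
        raise ZeroDivisionError("apical AUC is zero; ratio undefined")
    return (fit.basal_amp * fit.basal_sigma) / denom


def bin_ratios(
    ratios_by_group: dict[str, "np.ndarray | list[float]"],
    bin_width: float = 0.05,
) -> RatioHistogram:
    """Histogram ratios into left-closed bins aligned to multiples of bin_width.

    Percentages are per group (each group sums to 100); reported bin centres
    span the occupied range across all groups.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arrays = {}
    for group, vals in ratios_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {group!r} is empty")
        if np.any(arr <= 0):
            raise ValueError(f"group {group!r} contains non-positive ratios")
        arrays[group] = arr
    lo = min(int(np.floor(a.min() / bin_width)) for a in arrays.values())
    hi = max(int(np.floor(a.max() / bin_width)) for a in arrays.values())
    idx_range = np.arange(lo, hi + 1)
    centers = (idx_range + 0.5) * bin_width
    percentages = {}
    for group, arr in arrays.items():
        idx = np.floor(arr / bin_width).astype(int)
        counts = np.array([(idx == i).sum() for i in idx_range], dtype=float)
        percentages[group] = 100.0 * counts / counts.sum()
    return RatioHistogram(bin_width=bin_width, bin_centers=centers, percentages=percentages)
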
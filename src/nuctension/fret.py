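"""Bleed-through-corrected per-nucleus FRET indexing over a nuclear-envelope band.

Three-channel sensitized-emission sets (donor, acceptor, FRET) are reduced to
a per-pixel normalized index

    NFRET = (I_F - BT_d * I_D - BT_a * I_A) / sqrt(I_D * I_A)

on background-subtracted intensities, averaged over a thin band straddling
each nucleus boundary.  Bleed-through coefficients are calibrated from
single-fluorophore control fields.  Populations are reported relative to the
median of a no-tension control group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import BandError, CalibrationError

logger = logging.getLogger(__name__)

__all__ = [
    "FretImageSet",
    "BleedthroughModel",
    "NucleusFret",
    "segment_nuclei",
    "make_ne_band",
    "estimate_background",
    "estimate_bleedthrough",
    "compute_fret_map",
    "normalize_to_control",
]

_S8 = np.ones((3, 3), dtype=bool)


@dataclass
class FretImageSet:
    """Co-registered donor / acceptor / FRET channel images for one field."""

    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray
    pixel_size: float = 1.0
    field_id: str = ""

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        if not (self.donor.shape == self.acceptor.shape == self.fret.shape):
            raise ValueError("channel shapes differ")
        for name, img in (("donor", self.donor), ("acceptor", self.acceptor), ("fret", self.fret)):
            if np.any(img < 0):
                raise ValueError(f"negative intensities in {name} channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.donor.shape


@dataclass
class BleedthroughModel:
    """Donor-leakage and acceptor cross-excitation coefficients.

    ``constant`` holds intercepts only; ``linear`` adds a slope against the
    (background-subtracted) source-channel intensity.  Evaluated
    coefficients are clamped to >= 0.
    """

    bt_donor_intercept: float
    bt_acceptor_intercept: float
    bt_donor_slope: float = 0.0
    bt_acceptor_slope: float = 0.0
    model_kind: str = "constant"
    n_calibration_pixels: int = 0

    def __post_init__(self):
        if self.model_kind not in ("constant", "linear"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        for name in ("bt_donor_intercept", "bt_acceptor_intercept"):
            if getattr(self, name) < 0:
                warnings.warn(f"negative fitted {name}; clamped to 0")
                setattr(self, name, 0.0)

    def bt_donor(self, intensity) -> np.ndarray:
        return np.maximum(self.bt_donor_intercept + self.bt_donor_slope * np.asarray(intensity), 0.0)

    def bt_acceptor(self, intensity) -> np.ndarray:
        return np.maximum(
            self.bt_acceptor_intercept + self.bt_acceptor_slope * np.asarray(intensity), 0.0
        )


@dataclass
class NucleusFret:
    """Per-nucleus FRET index over its nuclear-envelope band."""

    nucleus_id: int
    band_mask: np.ndarray
    nfret_mean: float
    nfret_pixels: int
    relative_index: float = float("nan")


def segment_nuclei(image: np.ndarray, min_area: int = 100) -> np.ndarray:
    """Label nuclei in a single-channel image by Otsu threshold.

    Holes are filled (annular envelope signal becomes a solid nucleus),
    objects under ``min_area`` removed.  A blank image yields an empty
    labeling with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.ptp(image) == 0:
        warnings.warn("blank image: no nuclei found")
        return np.zeros(image.shape, dtype=np.int32)
    mask = image > threshold_otsu(image)
    mask = ndimage.binary_fill_holes(mask)
    labels = sk_label(mask, connectivity=2)
    for region in regionprops(labels):
        if region.area < min_area:
            labels[labels == region.label] = 0
    labels, _, _ = _relabel(labels)
    if labels.max() == 0:
        warnings.warn("no nuclei found above min_area")
    return labels


def _relabel(labels: np.ndarray):
    ids = np.unique(labels)
    ids = ids[ids != 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out, ids, len(ids)


def make_ne_band(nucleus_mask: np.ndarray, width: int = 3) -> np.ndarray:
    """Band straddling the mask boundary: dilate(1) minus erode(width - 1).

    Uses a 3x3 square structuring element (8-connectivity).  Raises
    :class:`BandError` when the mask erodes to empty, i.e. the object is
    thinner than the requested band.
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    if width < 1:
        raise ValueError("width must be >= 1")
    dilated = ndimage.binary_dilation(mask, structure=_S8)
    if width == 1:
        eroded = mask
    else:
        eroded = ndimage.binary_erosion(mask, structure=_S8, iterations=width - 1)
    if mask.any() and not eroded.any() and width > 1:
        raise BandError(f"mask erodes to empty at band width {width}; object too thin")
    return dilated & ~eroded


def estimate_background(image: np.ndarray, labels: np.ndarray | None = None) -> float:
    """Median intensity outside all (dilated) labeled objects.

    With no labels, objects are first found by Otsu; a blank image returns
    its constant value.
    """
    image = np.asarray(image, dtype=float)
    if labels is None:
        if np.ptp(image) == 0:
            return float(image.flat[0])
        labels = segment_nuclei(image, min_area=1)
    outside = ~ndimage.binary_dilation(labels > 0, structure=_S8, iterations=3)
    if not outside.any():
        raise ValueError("no background pixels left outside dilated objects")
    return float(np.median(image[outside]))


def _noise_sd(image: np.ndarray, outside: np.ndarray) -> float:
    """Robust (MAD-based) noise sd of background pixels."""
    vals = image[outside]
    return float(1.4826 * np.median(np.abs(vals - np.median(vals))))


def _calibration_pixels(image_set: FretImageSet, source: str):
    """Background-subtracted (source, fret) pixel pairs above the signal floor."""
    src = image_set.donor if source == "donor" else image_set.acceptor
    if np.ptp(src) == 0:
        return np.empty(0), np.empty(0)
    labels = segment_nuclei(src, min_area=20)
    if labels.max() == 0:
        return np.empty(0), np.empty(0)
    outside = ~ndimage.binary_dilation(labels > 0, structure=_S8, iterations=3)
    bg_src = float(np.median(src[outside]))
    bg_fret = float(np.median(image_set.fret[outside]))
    sd = _noise_sd(src, outside)
    floor = max(5.0 * sd, 1e-9)
    inside = labels > 0
    s = src[inside] - bg_src
    f = image_set.fret[inside] - bg_fret
    keep = s > floor
    return s[keep], f[keep]


def estimate_bleedthrough(
    donor_only: list[FretImageSet],
    acceptor_only: list[FretImageSet],
    model_kind: str = "constant",
    min_pixels: int = 100,
) -> BleedthroughModel:
    """Fit bleed-through coefficients from single-fluorophore control fields.

    Donor leakage comes from donor-only fields as the ratio
    (I_F - bg) / (I_D - bg) over valid object pixels (constant: median of
    ratios; linear: least squares of ratio against intensity); acceptor
    cross-excitation symmetrically from acceptor-only fields.
    """
    if not donor_only or not acceptor_only:
        raise CalibrationError("both donor-only and acceptor-only control sets required")

    def fit(sets, source):
        xs, ys = [], []
        for s in sets:
            x, y = _calibration_pixels(s, source)
            xs.append(x)
            ys.append(y)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size < min_pixels:
            raise CalibrationError(
                f"only {x.size} valid {source}-only calibration pixels (< {min_pixels})"
            )
        ratio = y / x
        if model_kind == "constant":
            return float(np.median(ratio)), 0.0, x.size
        if model_kind == "linear":
            slope, intercept = np.polyfit(x, ratio, 1)
            return float(intercept), float(slope), x.size
        raise ValueError(f"unknown model_kind {model_kind!r}")

    btd_i, btd_s, n_d = fit(donor_only, "donor")
    bta_i, bta_s, n_a = fit(acceptor_only, "acceptor")
    return BleedthroughModel(
        bt_donor_intercept=btd_i,
        bt_donor_slope=btd_s,
        bt_acceptor_intercept=bta_i,
        bt_acceptor_slope=bta_s,
        model_kind=model_kind,
        n_calibration_pixels=n_d + n_a,
    )


def compute_nfret_image(
    image_set: FretImageSet,
    bt: BleedthroughModel,
    background: tuple[float, float, float],
    validity_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel NFRET map and validity mask over a whole field."""
    bg_d, bg_a, bg_f = background
    d = image_set.donor - bg_d
    a = image_set.acceptor - bg_a
    f = image_set.fret - bg_f
    valid = (d > validity_threshold) & (a > validity_threshold)
    nfret = np.full(d.shape, np.nan)
    dv, av, fv = d[valid], a[valid], f[valid]
    nfret[valid] = (fv - bt.bt_donor(dv) * dv - bt.bt_acceptor(av) * av) / np.sqrt(dv * av)
    return nfret, valid


def compute_fret_map(
    image_set: FretImageSet,
    bt: BleedthroughModel,
    labels: np.ndarray | None = None,
    band_width: int = 3,
    background: tuple[float, float, float] | None = None,
    min_pixels: int = 50,
    validity_k: float = 3.0,
) -> tuple[list[NucleusFret], np.ndarray]:
    """Per-nucleus mean NFRET over the nuclear-envelope band.

    Band pixels require both background-subtracted donor and acceptor above
    ``validity_k`` times the background noise sd; nuclei with fewer than
    ``min_pixels`` valid band pixels are dropped (logged).  Returns the kept
    nuclei and the full-field per-pixel NFRET image (NaN off-band/invalid).
    """
    if labels is None:
        labels = segment_nuclei(image_set.acceptor)
    outside = ~ndimage.binary_dilation(labels > 0, structure=_S8, iterations=3)
    if background is None:
        background = tuple(
            float(np.median(ch[outside]))
            for ch in (image_set.donor, image_set.acceptor, image_set.fret)
        )
    noise = max(
        _noise_sd(image_set.donor, outside), _noise_sd(image_set.acceptor, outside)
    )
    thr = max(validity_k * noise, 1e-9)
    nfret_img, valid = compute_nfret_image(image_set, bt, background, thr)

    results: list[NucleusFret] = []
    out_map = np.full(image_set.shape, np.nan)
    for lab in range(1, int(labels.max()) + 1):
        mask = labels == lab
        if not mask.any():
            continue
        try:
            band = make_ne_band(mask, band_width)
        except BandError as exc:
            logger.info("nucleus %d dropped: %s", lab, exc)
            continue
        sel = band & valid
        n = int(sel.sum())
        if n < min_pixels:
            logger.info(
                "nucleus %d dropped: %d valid band pixels (< %d)", lab, n, min_pixels
            )
            continue
        out_map[sel] = nfret_img[sel]
        results.append(
            NucleusFret(
                nucleus_id=lab,
                band_mask=band,
                nfret_mean=float(np.nanmean(nfret_img[sel])),
                nfret_pixels=n,
            )
        )
    if not results:
        warnings.warn("no nucleus passed the validity/min_pixels filters")
    return results, out_map


def normalize_to_control(values, control_values) -> tuple[np.ndarray, np.ndarray]:
    """Scale both groups by the control median so the control median is 1."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    med = float(np.median(control))
    if med <= 0:
        raise ValueError(f"control median must be positive, got {med}")
    return values / med, control / med
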
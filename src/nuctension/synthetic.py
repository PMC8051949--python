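"""Synthetic inputs with known ground truth for every pipeline stage.

Every simulator is a pure function of its config (seed included): the same
config yields bit-identical output.  With noise disabled, simulated
observables equal their closed-form expectations exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .colony import ColonyMap
from .errors import PlacementError
from .fret import FretImageSet
from .lamin import ZProfile, two_gaussian_model
from .regions import GenomicRegion, PeakSet

__all__ = [
    "FretSimConfig",
    "ProfileSimConfig",
    "ColonySimConfig",
    "PeakSimConfig",
    "NucleusTruth",
    "simulate_fret_image_set",
    "simulate_z_profile",
    "simulate_colony",
    "simulate_peak_sets",
    "simulate_ct_table",
]

_S8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# FRET image sets


@dataclass
class FretSimConfig:
    """Forward model for a three-cube sensitized-emission acquisition.

    On the nuclear-envelope annulus the expected (pre-noise) signals are::

        I_D = S * (1 - E) * g_donor + background
        I_A = S * x_acceptor * g_acceptor + background
        I_F = bt_donor * (I_D - bg) + bt_acceptor * (I_A - bg)
              + S * E * g_fret + background

    ``mode`` selects full sensor fields ("both") or single-fluorophore
    bleed-through controls ("donor_only" / "acceptor_only").
    """

    n_nuclei: int = 30
    image_shape: tuple[int, int] = (512, 512)
    nucleus_radius_px: tuple[float, float] = (12.0, 18.0)
    ne_thickness_px: int = 3
    efficiency: float = 0.3
    expression_level: float = 2000.0
    bt_donor: float = 0.25
    bt_acceptor: float = 0.10
    background: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    g_donor: float = 1.0
    g_acceptor: float = 1.0
    g_fret: float = 1.0
    x_acceptor: float = 1.0
    mode: str = "both"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        if self.bt_donor < 0 or self.bt_acceptor < 0:
            raise ValueError("bleed-through fractions must be >= 0")
        if self.mode not in ("both", "donor_only", "acceptor_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        rmax = self.nucleus_radius_px[1]
        h, w = self.image_shape
        if (2 * rmax + 8) ** 2 * self.n_nuclei > h * w * 0.9:
            raise ValueError("image too small to host all nuclei without overlap")


@dataclass
class NucleusTruth:
    nucleus_id: int
    centroid: tuple[float, float]
    mask: np.ndarray
    annulus: np.ndarray
    efficiency: float


def _place_nuclei(config: FretSimConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse centres and radii."""
    h, w = config.image_shape
    rmin, rmax = config.nucleus_radius_px
    placed = []  # (cy, cx, ry, rx)
    margin = 4  # keeps annuli (dilated by 1) clear of each other and the border
    for _ in range(config.n_nuclei):
        for attempt in range(2000):
            ry = rng.uniform(rmin, rmax)
            rx = rng.uniform(rmin, rmax)
            cy = rng.uniform(ry + margin, h - ry - margin)
            cx = rng.uniform(rx + margin, w - rx - margin)
            ok = all(
                np.hypot(cy - py, cx - px) > (max(ry, rx) + max(pry, prx) + margin)
                for py, px, pry, prx in placed
            )
            if ok:
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {len(placed) + 1}/{config.n_nuclei} "
                f"after bounded retries"
            )
    return placed


def _annulus(mask: np.ndarray, width: int) -> np.ndarray:
    dilated = ndimage.binary_dilation(mask, structure=_S8)
    eroded = mask if width == 1 else ndimage.binary_erosion(mask, structure=_S8, iterations=width - 1)
    return dilated & ~eroded


def expected_fret_signals(config: FretSimConfig) -> tuple[float, float, float]:
    """Closed-form expected on-annulus (I_D, I_A, I_F) for a config."""
    S, E, bg = config.expression_level, config.efficiency, config.background
    if config.mode == "donor_only":
        i_d = S * config.g_donor + bg
        i_a = bg
        i_f = config.bt_donor * (i_d - bg) + bg
    elif config.mode == "acceptor_only":
        i_d = bg
        i_a = S * config.x_acceptor * config.g_acceptor + bg
        i_f = config.bt_acceptor * (i_a - bg) + bg
    else:
        i_d = S * (1 - E) * config.g_donor + bg
        i_a = S * config.x_acceptor * config.g_acceptor + bg
        i_f = (
            config.bt_donor * (i_d - bg)
            + config.bt_acceptor * (i_a - bg)
            + S * E * config.g_fret
            + bg
        )
    return i_d, i_a, i_f


def simulate_fret_image_set(
    config: FretSimConfig,
) -> tuple[FretImageSet, list[NucleusTruth]]:
    """Render a field of annular nuclear-envelope sensor signals plus truth.

    Nuclei are ellipses with a uniform-intensity envelope annulus of the
    configured thickness; Poisson shot noise is applied to expected counts
    (when enabled) followed by additive Gaussian read noise.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    placed = _place_nuclei(config, rng)
    yy, xx = np.mgrid[0:h, 0:w]

    i_d, i_a, i_f = expected_fret_signals(config)
    bg = config.background
    donor = np.full((h, w), bg)
    acceptor = np.full((h, w), bg)
    fret = np.full((h, w), bg)
    truths = []
    for k, (cy, cx, ry, rx) in enumerate(placed, start=1):
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        annulus = _annulus(mask, config.ne_thickness_px)
        donor[annulus] = i_d
        acceptor[annulus] = i_a
        fret[annulus] = i_f
        truths.append(
            NucleusTruth(
                nucleus_id=k,
                centroid=(cy, cx),
                mask=mask,
                annulus=annulus,
                efficiency=config.efficiency,
            )
        )

    def add_noise(img):
        if config.shot_noise:
            img = rng.poisson(img).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        return np.clip(img, 0.0, None)

    image_set = FretImageSet(
        donor=add_noise(donor),
        acceptor=add_noise(acceptor),
        fret=add_noise(fret),
        field_id=f"sim-seed{config.seed}",
    )
    return image_set, truths


# ---------------------------------------------------------------------------
# Axial profiles


@dataclass
class ProfileSimConfig:
    """Two-Gaussian-plus-baseline axial profile generator."""

    n_points: int = 60
    spacing: float = 0.13
    apical_amp: float = 100.0
    basal_amp: float = 100.0
    apical_mu: float = 2.0
    basal_mu: float = 5.0
    apical_sigma: float = 0.4
    basal_sigma: float = 0.4
    baseline: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.apical_mu >= self.basal_mu:
            raise ValueError("profile runs apical to basal: apical_mu < basal_mu")
        if self.apical_sigma <= 0 or self.basal_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if self.apical_amp < 0 or self.basal_amp < 0:
            raise ValueError("amplitudes must be >= 0")


def simulate_z_profile(config: ProfileSimConfig) -> tuple[ZProfile, dict]:
    """Sampled two-Gaussian profile plus ground-truth parameters.

    The truth dict carries the generating parameters, the true basal/apical
    AUC ratio, and an ``unresolved`` flag when the peaks are closer than
    twice the wider sigma.
    """
    rng = np.random.default_rng(config.seed)
    z = np.arange(config.n_points) * config.spacing
    clean = two_gaussian_model(
        z,
        config.baseline,
        config.apical_amp,
        config.apical_mu,
        config.apical_sigma,
        config.basal_amp,
        config.basal_mu,
        config.basal_sigma,
    )
    noisy = clean + (rng.normal(0.0, config.noise_sd, size=z.shape) if config.noise_sd > 0 else 0.0)
    profile = ZProfile(positions=z, intensities=noisy, nucleus_id=f"sim-{config.seed}")
    truth = dataclasses.asdict(config)
    truth["true_ratio"] = (config.basal_amp * config.basal_sigma) / (
        config.apical_amp * config.apical_sigma
    )
    truth["unresolved"] = bool(
        config.basal_mu - config.apical_mu < 2 * max(config.apical_sigma, config.basal_sigma)
    )
    return profile, truth


# ---------------------------------------------------------------------------
# Colonies


@dataclass
class ColonySimConfig:
    """Contiguous colony of lattice cells with position-dependent positivity."""

    n_cells: int = 100
    colony_radius: float = 7.0  # in cell diameters
    p_positive_interior: float = 0.6
    p_positive_periphery: float = 0.2
    cell_px: int = 8
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_positive_interior, self.p_positive_periphery):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


def _brute_force_periphery(label_mask: np.ndarray) -> dict[int, bool]:
    """Independent pixel-scan oracle: label -> touches background (8-adjacency)."""
    h, w = label_mask.shape
    out: dict[int, bool] = {}
    for y in range(h):
        for x in range(w):
            lab = label_mask[y, x]
            if lab == 0:
                continue
            out.setdefault(int(lab), False)
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and label_mask[ny, nx] == 0:
                        out[int(lab)] = True
    return out


def simulate_colony(config: ColonySimConfig) -> tuple[ColonyMap, pd.DataFrame]:
    """Contiguous colony on a square lattice inside a disk, with truth labels.

    Cells are unit lattice squares rendered at ``cell_px`` pixels; the
    ``n_cells`` lattice sites nearest the colony centre are used, which
    yields a single connected colony.  Truth compartments come from an
    independent brute-force background-adjacency scan.
    """
    rng = np.random.default_rng(config.seed)
    r = int(np.ceil(config.colony_radius))
    sites = [
        (i, j)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        if np.hypot(i, j) <= config.colony_radius
    ]
    if len(sites) < config.n_cells:
        raise PlacementError(
            f"{config.n_cells} cells do not fit in a disk of radius "
            f"{config.colony_radius} ({len(sites)} sites)"
        )
    sites.sort(key=lambda ij: (np.hypot(*ij), ij))
    chosen = sites[: config.n_cells]

    imin = min(i for i, _ in chosen)
    jmin = min(j for _, j in chosen)
    nrows = max(i for i, _ in chosen) - imin + 1
    ncols = max(j for _, j in chosen) - jmin + 1
    px = config.cell_px
    pad = px  # keep colony clear of the image border
    label_mask = np.zeros((nrows * px + 2 * pad, ncols * px + 2 * pad), dtype=np.int32)
    for lab, (i, j) in enumerate(chosen, start=1):
        y0 = pad + (i - imin) * px
        x0 = pad + (j - jmin) * px
        label_mask[y0 : y0 + px, x0 : x0 + px] = lab

    periphery = _brute_force_periphery(label_mask)
    rows = []
    for lab, (i, j) in enumerate(chosen, start=1):
        comp = "periphery" if periphery[lab] else "interior"
        p = config.p_positive_periphery if comp == "periphery" else config.p_positive_interior
        rows.append(
            {
                "label": lab,
                "x": pad + (j - jmin + 0.5) * px,
                "y": pad + (i - imin + 0.5) * px,
                "compartment_true": comp,
                "positive": bool(rng.random() < p),
            }
        )
    truth = pd.DataFrame(rows)
    cmap = ColonyMap(
        cells=truth[["label", "x", "y", "positive"]].copy(),
        label_mask=label_mask,
        colony_id=f"sim-{config.seed}",
    )
    return cmap, truth


# ---------------------------------------------------------------------------
# Peak sets


@dataclass
class PeakSimConfig:
    """Paired interval sets with a controlled shared/unique structure."""

    region: GenomicRegion = field(
        default_factory=lambda: GenomicRegion("chr3", 0, 1_000_000, "sim")
    )
    n_shared: int = 16
    n_only_a: int = 3
    n_only_b: int = 18
    peak_width: tuple[int, int] = (200, 600)
    min_gap: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.n_shared, self.n_only_a, self.n_only_b) < 0:
            raise ValueError("counts must be >= 0")
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1")
        n = self.n_shared + self.n_only_a + self.n_only_b
        needed = n * self.peak_width[1] + (n + 1) * self.min_gap
        if needed > self.region.length:
            raise PlacementError(
                f"region of {self.region.length} bp cannot host {n} peaks "
                f"of width <= {self.peak_width[1]} with gap {self.min_gap}"
            )


def simulate_peak_sets(
    config: PeakSimConfig,
) -> tuple[PeakSet, PeakSet, dict[str, int]]:
    """Two peak sets over one region with exact maintained/gained/lost truth.

    Peaks occupy disjoint slots separated by >= min_gap; shared slots carry
    a peak in both sets (B's copy jittered but overlapping >= 1 bp), unique
    slots carry a peak in one set only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_shared + config.n_only_a + config.n_only_b
    kinds = ["shared"] * config.n_shared + ["a"] * config.n_only_a + ["b"] * config.n_only_b
    rng.shuffle(kinds)

    widths = rng.integers(config.peak_width[0], config.peak_width[1] + 1, size=n)
    slack = config.region.length - int(widths.sum()) - (n + 1) * config.min_gap
    extra = np.sort(rng.integers(0, slack + 1, size=n)) if slack > 0 else np.zeros(n, int)
    extra = np.diff(np.concatenate([[0], extra]))  # non-negative spacing jitter

    a_peaks, b_peaks = [], []
    cursor = config.region.start + config.min_gap
    for k, (kind, width) in enumerate(zip(kinds, widths)):
        start = cursor + int(extra[k])
        end = start + int(width)
        peak = GenomicRegion(config.region.chrom, start, end)
        if kind == "shared":
            a_peaks.append(peak)
            # overlapping partner: shift within the slot, keeping >= 1 bp shared
            max_shift = min(int(width) - 1, config.min_gap // 2)
            shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift > 0 else 0
            b_peaks.append(GenomicRegion(config.region.chrom, start + shift, end + shift))
        elif kind == "a":
            a_peaks.append(peak)
        else:
            b_peaks.append(peak)
        cursor = end + config.min_gap
    truth = {
        "maintained": config.n_shared,
        "gained_in_b": config.n_only_b,
        "lost_in_b": config.n_only_a,
    }
    return (
        PeakSet(condition="A", peaks=a_peaks),
        PeakSet(condition="B", peaks=b_peaks),
        truth,
    )


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(
    fold_changes: dict[str, dict[str, float]],
    reference_condition: str,
    housekeeping: str = "Gapdh",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    housekeeping_ct: float = 20.0,
    reference_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """qPCR Ct table whose noiseless Livak estimate equals the given folds.

    ``fold_changes`` maps gene -> condition -> true fold change relative to
    ``reference_condition`` (whose fold must be 1 or absent).  Each Ct
    measurement gets independent Gaussian noise of ``noise_sd`` cycles.
    """
    if not fold_changes:
        raise ValueError("no genes given")
    rng = np.random.default_rng(seed)
    conditions: list[str] = [reference_condition]
    for per_gene in fold_changes.values():
        for cond in per_gene:
            if cond not in conditions:
                conditions.append(cond)
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            hk_ct = housekeeping_ct + rng.normal(0.0, noise_sd) if noise_sd else housekeeping_ct
            rows.append(
                {
                    "sample_id": sample,
                    "condition": cond,
                    "gene": housekeeping,
                    "ct": hk_ct,
                    "replicate": rep,
                }
            )
            for gene, per_gene in fold_changes.items():
                if gene == housekeeping:
                    raise ValueError("housekeeping gene cannot carry a fold change")
                fold = 1.0 if cond == reference_condition else per_gene.get(cond, 1.0)
                ct = hk_ct + reference_delta_ct - np.log2(fold)
                if noise_sd:
                    ct += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "sample_id": sample,
                        "condition": cond,
                        "gene": gene,
                        "ct": float(ct),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)
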
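"""Radial-intensity quantification of cell-cluster co-culture images.

A tumour-cell cluster shows up as a disc in the fluorescence channel; T cells
accumulating around it form a ring in the bright-field (cell-density) channel.
Both channels are Gaussian-smoothed, radial intensity profiles are taken
about the cluster centre, min-max normalised, and subtracted; the maximum of
the difference profile is the per-cluster ring statistic, compared across
groups with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components

DEFAULT_SIGMA_UM = 14.4
DEFAULT_PIXEL_SIZE_UM = 1.3


@dataclass
class ImagePair:
    bright_field: np.ndarray
    fluorescence: np.ndarray
    pixel_size: float  # micrometres per pixel
    group: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.bright_field = np.asarray(self.bright_field, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.bright_field.shape != self.fluorescence.shape:
            raise ValueError("channel shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name, img in (("bright_field", self.bright_field), ("fluorescence", self.fluorescence)):
            if not np.isfinite(img).all():
                raise ValueError(f"{name} contains non-finite pixels")
            if (img < 0).any():
                raise ValueError(f"{name} contains negative intensities")


@dataclass
class ClusterProfile:
    centre: tuple[float, float]  # (row, col) pixels
    bin_edges_um: np.ndarray
    bf_profile: np.ndarray
    fl_profile: np.ndarray
    bf_normalized: np.ndarray
    fl_normalized: np.ndarray
    difference: np.ndarray
    max_intensity_difference: float
    degenerate: bool = False
    truncated: bool = False
    empty_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def generate_cluster_image(
    cluster_radius_um: float = 60.0,
    ring_offset_um: float = 10.0,
    ring_width_um: float = 20.0,
    ring_amplitude: float = 0.6,
    disc_amplitude: float = 1.0,
    background: float = 0.05,
    noise_sd: float = 0.02,
    image_size: int = 256,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    centre: tuple[float, float] | None = None,
    seed: int = 0,
    group: str = "",
    replicate: str = "",
) -> ImagePair:
    """Synthetic co-culture pair: fluorescent disc; bright-field disc plus a
    T-cell ring centred ``cluster_radius + ring_offset`` µm from the centre.

    Bright-field uses the high-intensity-equals-cell-dense convention.
    Deterministic per seed; intensities clipped to be non-negative.
    """
    if cluster_radius_um <= 0:
        raise ValueError("cluster radius must be positive")
    rng = np.random.default_rng(seed)
    if centre is None:
        margin = (cluster_radius_um + ring_offset_um + ring_width_um) / pixel_size + 2
        lo, hi = margin, image_size - margin
        if hi <= lo:
            raise ValueError("geometry does not fit in the image")
        centre = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))

    rows, cols = np.mgrid[0:image_size, 0:image_size]
    r_um = np.hypot(rows - centre[0], cols - centre[1]) * pixel_size
    disc = (r_um <= cluster_radius_um).astype(float)
    ring_centre = cluster_radius_um + ring_offset_um
    ring = (np.abs(r_um - ring_centre) <= ring_width_um / 2).astype(float)

    fl = background + disc_amplitude * disc
    bf = background + disc_amplitude * disc + ring_amplitude * ring
    if noise_sd > 0:
        fl = fl + rng.normal(0.0, noise_sd, fl.shape)
        bf = bf + rng.normal(0.0, noise_sd, bf.shape)
    return ImagePair(
        np.clip(bf, 0.0, None), np.clip(fl, 0.0, None), pixel_size, group, replicate
    )


def smooth(image: np.ndarray, sigma_um: float = DEFAULT_SIGMA_UM,
           pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Gaussian smoothing with sigma given in µm, reflective boundary."""
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if sigma_um < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_um == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma_um / pixel_size, mode="reflect")


def radial_profile(
    image: np.ndarray,
    centre: tuple[float, float],
    max_radius_um: float,
    bin_width_um: float,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Mean intensity per radial bin [k*w, (k+1)*w) µm about ``centre``.

    Returns (bin_edges_um, profile, empty_bin_mask, truncated_flag); bins
    beyond the nearest image edge are dropped with the truncated flag set,
    remaining empty bins are NaN and flagged.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cr, cc = centre
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError("centre outside image")
    edge_dist_um = min(cr, h - 1 - cr, cc, w - 1 - cc) * pixel_size
    truncated = False
    if max_radius_um > edge_dist_um:
        max_radius_um = edge_dist_um
        truncated = True
    n_bins = max(1, int(np.floor(max_radius_um / bin_width_um)))
    edges = np.arange(n_bins + 1) * bin_width_um

    rows, cols = np.mgrid[0:h, 0:w]
    r_um = np.hypot(rows - cr, cols - cc) * pixel_size
    idx = np.floor(r_um / bin_width_um).astype(int)
    in_range = idx < n_bins
    sums = np.bincount(idx[in_range], weights=image[in_range], minlength=n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    empty = counts == 0
    return edges, profile, empty, truncated


def _minmax(profile: np.ndarray) -> tuple[np.ndarray, bool]:
    finite = profile[np.isfinite(profile)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return np.zeros_like(profile), True
    lo, hi = finite.min(), finite.max()
    return (profile - lo) / (hi - lo), False


def normalize_and_subtract(
    bf_profile: np.ndarray, fl_profile: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Min-max normalise both profiles, subtract (bright-field minus
    fluorescence) and take the maximum of the difference.

    A constant profile cannot be normalised: it is zeroed and the cluster
    flagged degenerate.  Returns (difference profile, statistic, degenerate).
    """
    bf_profile = np.asarray(bf_profile, dtype=float)
    fl_profile = np.asarray(fl_profile, dtype=float)
    if bf_profile.shape != fl_profile.shape:
        raise ValueError("profiles differ in length")
    bf_n, bf_degen = _minmax(bf_profile)
    fl_n, fl_degen = _minmax(fl_profile)
    diff = bf_n - fl_n
    finite = diff[np.isfinite(diff)]
    statistic = float(finite.max()) if finite.size else 0.0
    return diff, statistic, bf_degen or fl_degen


def detect_cluster_centre(
    fluorescence: np.ndarray, threshold: float | None = None
) -> tuple[float, float]:
    """Intensity-weighted centroid of the largest above-threshold component.

    Threshold defaults to Otsu's method on the fluorescence channel.
    """
    img = np.asarray(fluorescence, dtype=float)
    if threshold is None:
        if np.ptp(img) == 0:
            raise ValueError("no cluster found")
        threshold = threshold_otsu(img)
    mask = img > threshold
    labels = label_components(mask)
    if labels.max() == 0:
        raise ValueError("no cluster found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    component = labels == largest
    weights = img * component
    total = weights.sum()
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (float((rows * weights).sum() / total), float((cols * weights).sum() / total))


def profile_cluster(
    pair: ImagePair,
    sigma_um: float = DEFAULT_SIGMA_UM,
    bin_width_um: float | None = None,
    max_radius_um: float | None = None,
    centre: tuple[float, float] | None = None,
    invert_bright_field: bool = False,
) -> ClusterProfile:
    """Full per-cluster pipeline: smooth, locate, profile, normalise, score."""
    bf = pair.bright_field
    if invert_bright_field:
        bf = bf.max() - bf
    bf_s = smooth(bf, sigma_um, pair.pixel_size)
    fl_s = smooth(pair.fluorescence, sigma_um, pair.pixel_size)
    if centre is None:
        centre = detect_cluster_centre(fl_s)
    if bin_width_um is None:
        bin_width_um = pair.pixel_size
    if max_radius_um is None:
        h, w = fl_s.shape
        max_radius_um = min(centre[0], h - 1 - centre[0], centre[1], w - 1 - centre[1]) * pair.pixel_size
    edges, bf_prof, empty_bf, trunc_bf = radial_profile(
        bf_s, centre, max_radius_um, bin_width_um, pair.pixel_size
    )
    _, fl_prof, empty_fl, trunc_fl = radial_profile(
        fl_s, centre, max_radius_um, bin_width_um, pair.pixel_size
    )
    diff, statistic, degenerate = normalize_and_subtract(bf_prof, fl_prof)
    bf_n, _ = _minmax(bf_prof)
    fl_n, _ = _minmax(fl_prof)
    return ClusterProfile(
        centre=centre,
        bin_edges_um=edges,
        bf_profile=bf_prof,
        fl_profile=fl_prof,
        bf_normalized=bf_n,
        fl_normalized=fl_n,
        difference=diff,
        max_intensity_difference=statistic,
        degenerate=degenerate,
        truncated=trunc_bf or trunc_fl,
        empty_bins=empty_bf | empty_fl,
    )


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float]]  # (group_a, group_b, adjusted p)


def compare_groups(statistics: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA over per-cluster statistics plus Tukey-HSD pairwise p's.

    Identical data in every group (zero between- and within-group variance)
    yields F = 0, p = 1 by convention.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in statistics.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = len(groups) - 1
    df_within = values.size - len(groups)

    if ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))

    names = sorted(groups)
    pairwise: list[tuple[str, str, float]] = []
    if ss_within > 0:
        tukey = stats.tukey_hsd(*[groups[g] for g in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairwise.append((names[i], names[j], float(tukey.pvalue[i, j])))
    else:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                same = np.array_equal(groups[names[i]], groups[names[j]])
                pairwise.append((names[i], names[j], 1.0 if same else 0.0))
    return AnovaResult(float(f_stat), float(p), pairwise)


def results_to_tsv(
    profiles: Sequence[tuple[str, str, ClusterProfile]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("group\treplicate\tcentre_row\tcentre_col\tstatistic\tdegenerate\n")
        for group, replicate, prof in profiles:
            fh.write(
                f"{group}\t{replicate}\t{prof.centre[0]:.3f}\t{prof.centre[1]:.3f}\t"
                f"{prof.max_intensity_difference:.8g}\t{int(prof.degenerate)}\n"
            )


def anova_to_tsv(result: AnovaResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tstatistic\tp_value\n")
        fh.write(f"one_way_anova_F\t{result.f_statistic:.8g}\t{result.p_value:.8g}\n")
        for a, b, p in result.pairwise:
            fh.write(f"{a}_vs_{b}\ttukey_hsd\t{p:.8g}\n")
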
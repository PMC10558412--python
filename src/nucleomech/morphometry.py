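"""Nuclear segmentation and morphometry.

Covers the image statistics of the pipeline: nuclear area and
circularity, confinement / osmotic fold-changes, lamin B1 transversal
intensity profiles with peripheral/aberrant classification, and γH2AX
focus counting with the ">2 visible foci" high-damage call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, segmentation
from sklearn.base import BaseEstimator

from .core import Image2D, LabeledMask

__all__ = [
    "NucleusRecord",
    "NucleusSegmenter",
    "LaminProfileClassifier",
    "segment_nuclei",
    "nuclear_area",
    "circularity",
    "area_fold_change",
    "osmotic_classify",
    "extract_profile",
    "mean_profile",
    "classify_profile",
    "count_foci",
    "analyze_nuclei",
]


@dataclass
class NucleusRecord:
    """Per-nucleus morphometric measurements.

    ``high_foci`` is True iff ``foci_count > 2`` (the high-γH2AX call).
    """

    label: int
    area_um2: float
    circularity: float
    centroid_xy: tuple[float, float]
    profile: np.ndarray | None = None
    profile_class: str | None = None
    foci_count: int | None = None
    high_foci: bool | None = None
    condition: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

class NucleusSegmenter(BaseEstimator):
    """Transformer segmenting nuclei from a DAPI channel.

    Recipe: Gaussian smoothing (sigma in px) -> Otsu threshold -> hole
    filling -> removal of components below ``min_area_um2`` -> optional
    watershed split of touching nuclei on the distance transform.

    Attributes set by :meth:`fit` / :meth:`transform`:

    labels_ : LabeledMask of the last transformed image.
    """

    def __init__(
        self,
        min_area_um2: float = 5.0,
        split_touching: bool = False,
        sigma_px: float = 1.0,
        min_distance_um: float = 2.0,
    ):
        self.min_area_um2 = min_area_um2
        self.split_touching = split_touching
        self.sigma_px = sigma_px
        self.min_distance_um = min_distance_um

    def fit(self, X: Image2D, y=None) -> "NucleusSegmenter":
        if not isinstance(X, Image2D):
            raise TypeError("X must be an Image2D")
        return self

    def transform(self, X: Image2D) -> LabeledMask:
        self.fit(X)
        px = X.pixels
        smoothed = ndimage.gaussian_filter(px, self.sigma_px)
        if np.ptp(smoothed) <= 0:
            self.labels_ = LabeledMask(np.zeros(px.shape, dtype=np.int64))
            return self.labels_
        thr = filters.threshold_otsu(smoothed)
        fg = smoothed > thr
        fg = ndimage.binary_fill_holes(fg)
        min_px = int(np.ceil(self.min_area_um2 / X.pixel_size_um**2))
        if self.split_touching:
            dist = ndimage.distance_transform_edt(fg)
            min_dist_px = max(int(self.min_distance_um / X.pixel_size_um), 1)
            peaks = feature.peak_local_max(
                dist, min_distance=min_dist_px, labels=fg, exclude_border=False
            )
            markers = np.zeros(px.shape, dtype=np.int64)
            for i, (r, c) in enumerate(peaks, start=1):
                markers[r, c] = i
            labels = segmentation.watershed(-dist, markers, mask=fg)
        else:
            labels, _ = ndimage.label(fg)
        # drop small components and relabel consecutively
        out = np.zeros(px.shape, dtype=np.int64)
        nxt = 1
        for region in measure.regionprops(labels):
            if region.area >= min_px:
                out[labels == region.label] = nxt
                nxt += 1
        self.labels_ = LabeledMask(out)
        return self.labels_

    def fit_transform(self, X: Image2D, y=None) -> LabeledMask:
        return self.transform(X)


def segment_nuclei(
    dapi: Image2D, min_area_um2: float = 5.0, split_touching: bool = False, **kwargs
) -> LabeledMask:
    """Segment nuclei from a DAPI image (see :class:`NucleusSegmenter`)."""
    return NucleusSegmenter(
        min_area_um2=min_area_um2, split_touching=split_touching, **kwargs
    ).transform(dapi)


# ---------------------------------------------------------------------------
# Scalar morphometry
# ---------------------------------------------------------------------------

def nuclear_area(mask_region: np.ndarray, pixel_size_um: float) -> float:
    """Area in µm²: pixel count × pixel size squared."""
    region = np.asarray(mask_region, dtype=bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    return n * pixel_size_um**2


def _smoothed_contour(region: np.ndarray, smooth_sigma_px: float = 1.0) -> np.ndarray:
    """Sub-pixel boundary polygon of a binary region, lightly smoothed.

    The region is smoothed with a small Gaussian and contoured at the 0.5
    level, which removes pixelation staircase without eroding genuine
    corners at the scale of interest.
    """
    pad = int(np.ceil(3 * smooth_sigma_px)) + 2
    padded = np.pad(region.astype(float), pad)
    smoothed = ndimage.gaussian_filter(padded, smooth_sigma_px)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        raise ValueError("region has no contour")
    return max(contours, key=len) - pad


def circularity(mask_region: np.ndarray, smooth_sigma_px: float = 1.0) -> float:
    """Shape circularity 4*pi*area / perimeter**2 (1 for a circle).

    The perimeter is measured on the smoothed sub-pixel contour; the area
    is the polygon area of the same contour, keeping numerator and
    denominator mutually consistent. Regions touching the image border are
    measured but the caller should treat them as unreliable.
    """
    region = np.asarray(mask_region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    contour = _smoothed_contour(region, smooth_sigma_px)
    d = np.diff(contour, axis=0)
    perimeter = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    y, x = contour[:, 0], contour[:, 1]
    area = 0.5 * abs(float(np.dot(y[:-1], x[1:]) - np.dot(y[1:], x[:-1])))
    if perimeter <= 0:
        raise ValueError("degenerate contour")
    return 4.0 * np.pi * area / perimeter**2


def touches_border(mask_region: np.ndarray) -> bool:
    region = np.asarray(mask_region, dtype=bool)
    return bool(
        region[0, :].any() or region[-1, :].any() or region[:, 0].any() or region[:, -1].any()
    )


def area_fold_change(area_pre_um2: float, area_post_um2: float) -> float:
    """Fold change post/pre of nuclear area (e.g. under confinement)."""
    if area_pre_um2 <= 0 or area_post_um2 <= 0:
        raise ValueError("areas must be positive")
    return area_post_um2 / area_pre_um2


def osmotic_classify(
    area_pre_um2: float,
    area_post_um2: float,
    shrink_thresh: float = -0.10,
    swell_thresh: float = 0.10,
) -> str:
    """Classify the osmotic response of one nucleus from its area change.

    Relative change (post-pre)/pre below ``shrink_thresh`` -> ``"shrunk"``,
    above ``swell_thresh`` -> ``"swollen"``, else ``"unchanged"``.
    """
    if area_pre_um2 <= 0 or area_post_um2 <= 0:
        raise ValueError("areas must be positive")
    rel = (area_post_um2 - area_pre_um2) / area_pre_um2
    if rel < shrink_thresh:
        return "shrunk"
    if rel > swell_thresh:
        return "swollen"
    return "unchanged"


# ---------------------------------------------------------------------------
# Transversal intensity profiles (lamin B1)
# ---------------------------------------------------------------------------

def _region_axis(region: np.ndarray, axis: str, fixed_angle: float | None):
    """Centroid and unit vector of the requested transversal axis."""
    props = measure.regionprops(region.astype(np.uint8))[0]
    cy, cx = props.centroid
    if axis == "fixed_angle":
        if fixed_angle is None:
            raise ValueError("fixed_angle axis requires an angle")
        ang = fixed_angle
    else:
        # regionprops orientation: angle between major axis and vertical
        ang = np.pi / 2.0 - props.orientation
        if axis == "minor":
            ang += np.pi / 2.0
        elif axis != "major":
            raise ValueError(f"unknown axis {axis!r}")
    return (cy, cx), (np.sin(ang), np.cos(ang))


def extract_profile(
    channel: Image2D,
    mask_region: np.ndarray,
    axis: str = "major",
    n_samples: int = 101,
    fixed_angle: float | None = None,
) -> np.ndarray:
    """Sample a transversal intensity profile across one nucleus.

    The intensity is sampled along the chosen axis through the region
    centroid between the two boundary intersections; the abscissa is
    length-normalised to [0, 1] and the ordinate to the profile maximum.
    """
    region = np.asarray(mask_region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    (cy, cx), (dy, dx) = _region_axis(region, axis, fixed_angle)
    H, W = region.shape

    def march(sy, sx):
        """Distance from centroid to the mask boundary along (sy, sx)."""
        step = 0.25
        t = 0.0
        last_inside = 0.0
        while True:
            t += step
            y, x = cy + sy * t, cx + sx * t
            if not (0 <= y < H and 0 <= x < W):
                break
            if region[int(round(min(y, H - 1))), int(round(min(x, W - 1)))]:
                last_inside = t
            elif t - last_inside > 3:  # left the mask for good
                break
        return last_inside

    t_pos = march(dy, dx)
    t_neg = march(-dy, -dx)
    if t_pos <= 0 or t_neg <= 0:
        raise ValueError("axis does not intersect the mask boundary on both sides")
    ts = np.linspace(-t_neg, t_pos, n_samples)
    ys = cy + dy * ts
    xs = cx + dx * ts
    vals = ndimage.map_coordinates(channel.pixels, [ys, xs], order=1, mode="nearest")
    vmax = vals.max()
    return vals / vmax if vmax > 0 else vals


def mean_profile(profiles) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SD of equal-length normalised profiles."""
    arr = np.asarray(list(profiles), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need >= 1 equal-length profiles")
    sd = arr.std(axis=0, ddof=0)
    return arr.mean(axis=0), sd


def classify_profile(
    profile: np.ndarray,
    prominence: float = 0.2,
    outer_zone: float = 0.25,
    smooth_window: int = 5,
    score_outer: float = 0.20,
    score_central: float = 0.50,
) -> tuple[str, int, float]:
    """Classify a transversal lamin profile as peripheral or aberrant.

    A normally laminated nucleus shows two characteristic peaks at the
    ends of the transversal section (the nuclear periphery). Peaks are
    local maxima with prominence >= ``prominence`` x range after a light
    moving-average smoothing; the call is ``"peripheral"`` iff there are
    exactly 2 peaks and both lie in the outer ``outer_zone`` fraction of
    the abscissa. The peripheral-enrichment score is
    mean(outer 20 % bins) / mean(central 50 % bins).

    Returns ``(label, peak_count, score)``.
    """
    from scipy.signal import find_peaks

    p = np.asarray(profile, dtype=float)
    n = len(p)
    rng_ = float(np.ptp(p))
    # enrichment score
    n_out = max(int(round(score_outer / 2 * n)), 1)
    c0 = int(round((1 - score_central) / 2 * n))
    c1 = n - c0
    outer_mean = float(np.mean(np.concatenate([p[:n_out], p[-n_out:]])))
    central_mean = float(np.mean(p[c0:c1]))
    score = outer_mean / central_mean if central_mean > 0 else float("inf")
    if rng_ <= 0:
        return "aberrant", 0, 1.0
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ps = np.convolve(p, kernel, mode="same")
    else:
        ps = p
    # pad so boundary maxima register as peaks
    padded = np.concatenate([[ps.min()], ps, [ps.min()]])
    peaks, _ = find_peaks(padded, prominence=prominence * rng_)
    peaks = peaks - 1
    k = len(peaks)
    if k == 2:
        zone = outer_zone * (n - 1)
        if peaks[0] <= zone and peaks[1] >= (n - 1) - zone:
            return "peripheral", k, score
    return "aberrant", k, score


class LaminProfileClassifier(BaseEstimator):
    """Classifier wrapping :func:`classify_profile` over many profiles.

    Stateless (rule-based): ``fit`` validates, ``predict`` returns an
    array of ``"peripheral"`` / ``"aberrant"`` labels.
    """

    def __init__(
        self,
        prominence: float = 0.2,
        outer_zone: float = 0.25,
        smooth_window: int = 5,
    ):
        self.prominence = prominence
        self.outer_zone = outer_zone
        self.smooth_window = smooth_window

    def fit(self, X, y=None) -> "LaminProfileClassifier":
        np.asarray(X, dtype=float)
        return self

    def predict(self, X) -> np.ndarray:
        return np.array(
            [
                classify_profile(
                    p,
                    prominence=self.prominence,
                    outer_zone=self.outer_zone,
                    smooth_window=self.smooth_window,
                )[0]
                for p in np.asarray(X, dtype=float)
            ]
        )

    def score_samples(self, X) -> np.ndarray:
        """Peripheral-enrichment score per profile."""
        return np.array(
            [
                classify_profile(
                    p,
                    prominence=self.prominence,
                    outer_zone=self.outer_zone,
                    smooth_window=self.smooth_window,
                )[2]
                for p in np.asarray(X, dtype=float)
            ]
        )


# ---------------------------------------------------------------------------
# Foci counting (γH2AX)
# ---------------------------------------------------------------------------

def count_foci(
    foci_channel: Image2D,
    mask_region: np.ndarray,
    diameter_range_um: tuple[float, float] = (0.4, 1.6),
    rel_threshold: float = 1.5,
    high_cutoff: int = 2,
) -> tuple[int, bool]:
    """Count punctate foci inside one nucleus; flag high-damage nuclei.

    Laplacian-of-Gaussian blob detection over the physical diameter range,
    restricted to the mask; a blob is kept if its peak intensity is at
    least ``rel_threshold`` times the within-mask background median. The
    high call is ``foci_count > high_cutoff`` (">2 visible foci").
    """
    region = np.asarray(mask_region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    px = foci_channel.pixels
    psz = foci_channel.pixel_size_um
    # LoG blob radius ~ sigma * sqrt(2)
    sigma_min = diameter_range_um[0] / 2.0 / np.sqrt(2.0) / psz
    sigma_max = diameter_range_um[1] / 2.0 / np.sqrt(2.0) / psz
    masked = np.where(region, px, 0.0)
    rng_ = float(np.ptp(masked))
    if rng_ <= 0:
        return 0, False
    blobs = feature.blob_log(
        masked,
        min_sigma=sigma_min,
        max_sigma=sigma_max,
        num_sigma=8,
        threshold=0.05 * rng_,
        overlap=0.3,
    )
    # peaks are read off a lightly smoothed copy: raw single-pixel noise
    # excursions above the threshold would otherwise count as foci
    smoothed = ndimage.gaussian_filter(px, 1.0)
    background = float(np.median(smoothed[region]))
    count = 0
    H, W = px.shape
    for y, x, _s in blobs:
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < H and 0 <= ix < W) or not region[iy, ix]:
            continue
        peak = smoothed[iy, ix]
        if background > 0 and peak < rel_threshold * background:
            continue
        count += 1
    return count, count > high_cutoff


# ---------------------------------------------------------------------------
# Convenience: full per-image morphometry
# ---------------------------------------------------------------------------

def analyze_nuclei(
    channels: dict[str, Image2D],
    mask: LabeledMask | None = None,
    condition: str = "",
    profile_channel: str = "laminB1",
    foci_channel: str = "gH2AX",
    **segment_kwargs,
) -> list[NucleusRecord]:
    """Segment (if no mask given) and measure every nucleus in a field."""
    dapi = channels["DAPI"]
    if mask is None:
        mask = segment_nuclei(dapi, **segment_kwargs)
    records: list[NucleusRecord] = []
    for lab in np.unique(mask.labels[mask.labels > 0]):
        region = mask.region(int(lab))
        props = measure.regionprops(region.astype(np.uint8))[0]
        flags: list[str] = []
        if touches_border(region):
            flags.append("touches_border")
        rec = NucleusRecord(
            label=int(lab),
            area_um2=nuclear_area(region, dapi.pixel_size_um),
            circularity=circularity(region),
            centroid_xy=(props.centroid[1], props.centroid[0]),
            condition=condition,
            flags=tuple(flags),
        )
        if profile_channel in channels:
            try:
                rec.profile = extract_profile(channels[profile_channel], region)
                rec.profile_class = classify_profile(rec.profile)[0]
            except ValueError:
                rec.flags = rec.flags + ("degenerate_profile",)
        if foci_channel in channels:
            rec.foci_count, rec.high_foci = count_foci(channels[foci_channel], region)
        records.append(rec)
    return records
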
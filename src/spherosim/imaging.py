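"""Quantitative analysis of (synthetic) spheroid cryosection images.

Pipeline: median-filter smoothing of the nuclear (blue/HOECHST) channel,
watershed segmentation of the inverted intensity landscape restricted to
pixels above the nuclear threshold, per-nucleus marker classification
(pixel intensity threshold + positive-pixel-fraction threshold), spheroid
lumen estimation by dilation + hole filling, Voronoi-based cell-size
estimation, and border-distance binning of per-nucleus statistics.

A synthetic multichannel section generator provides pixel- and
nucleus-level ground truth for benchmarking the pipeline (real micrographs
are not part of the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree, QhullError
from skimage.segmentation import watershed
from skimage.measure import regionprops


@dataclass
class ImageParams:
    """Detection thresholds (intensities and nucleus-positive fractions)."""

    I_HOECHST: float = 0.15
    I_TUNEL: float = 0.45
    phi_TUNEL: float = 0.20
    I_Ki67: float = 0.35
    phi_Ki67: float = 0.05

    def __post_init__(self) -> None:
        for name in ("I_HOECHST", "I_TUNEL", "phi_TUNEL", "I_Ki67", "phi_Ki67"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class MultiChannelImage:
    """RGB section image; intensities in [0, 1); square pixels."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_size: float = 0.99  # um per pixel edge (pixel area ~0.98 um^2)

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("channels must share one shape")
        for ch in (self.red, self.green, self.blue):
            if ch.min() < 0 or ch.max() >= 1.0:
                raise ValueError("intensities must lie in [0, 1)")


@dataclass
class SegmentationResult:
    labels: np.ndarray                 # 0 = background
    props: list = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.props]) if self.props \
            else np.empty((0, 2))


@dataclass
class ClassificationMetrics:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else np.nan

    @property
    def TNR(self) -> float:
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else np.nan

    @property
    def error(self) -> float:
        n = self.TP + self.FP + self.TN + self.FN
        return (self.FP + self.FN) / n if n else np.nan


# -- filters ---------------------------------------------------------------


def median_filter(channel: np.ndarray, window: int = 3) -> np.ndarray:
    """n x n median with reflective edge padding (odd n >= 3)."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    return ndimage.median_filter(channel, size=window, mode="reflect")


def smooth_nuclei(channel: np.ndarray, passes: int = 4) -> np.ndarray:
    """Edge-preserving smoothing: repeated 3x3 median passes."""
    out = channel
    for _ in range(passes):
        out = median_filter(out, 3)
    return out


# -- segmentation & classification ----------------------------------------


def watershed_segment(channel: np.ndarray, seed_threshold: float = 0.15,
                      connectivity: int = 1) -> SegmentationResult:
    """Flooding watershed of the inverted intensity landscape 1 - I,
    restricted to pixels with I > seed_threshold.

    Each catchment basin becomes one nucleus label; pixels below the
    threshold are background.  Default 4-neighborhood flooding.
    """
    mask = channel > seed_threshold
    if not mask.any():
        return SegmentationResult(np.zeros(channel.shape, dtype=np.int32), [])
    labels = watershed(1.0 - channel, mask=mask, connectivity=connectivity)
    props = regionprops(labels)
    return SegmentationResult(labels.astype(np.int32), props)


def classify_nuclei(segmentation: SegmentationResult, marker: np.ndarray,
                    I_thresh: float, phi_thresh: float) -> dict[int, bool]:
    """Marker positivity per nucleus.

    A pixel is positive when its marker intensity reaches ``I_thresh``; a
    nucleus is positive when its positive-pixel fraction reaches
    ``phi_thresh``.
    """
    if not (0 <= I_thresh <= 1 and 0 <= phi_thresh <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    positive_px = marker >= I_thresh
    flags: dict[int, bool] = {}
    for p in segmentation.props:
        if p.area == 0:
            raise ValueError(f"empty nucleus label {p.label}")
        coords = tuple(p.coords.T)
        frac = positive_px[coords].mean()
        flags[p.label] = bool(frac >= phi_thresh)
    return flags


def compute_metrics(flags: dict[int, bool], gold: dict[int, bool]
                    ) -> ClassificationMetrics:
    """Confusion-matrix arithmetic against a gold standard over the same
    object set."""
    if set(flags) != set(gold):
        raise ValueError("label sets of flags and gold standard differ")
    tp = fp = tn = fn = 0
    for k, f in flags.items():
        g = gold[k]
        if f and g:
            tp += 1
        elif f and not g:
            fp += 1
        elif not f and not g:
            tn += 1
        else:
            fn += 1
    return ClassificationMetrics(TP=tp, FP=fp, TN=tn, FN=fn)


# -- lumen, border, cell sizes --------------------------------------------


def estimate_lumen_and_border(segmentation: SegmentationResult,
                              dilations: int = 3
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Approximate the spheroid lumen by inflating the nuclei mask
    (repeated 3x3 max filter), filling interior holes; the border is the
    set of lumen pixels adjacent to background.
    """
    if segmentation.n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    mask = segmentation.labels > 0
    selem = np.ones((3, 3), dtype=bool)
    # 3x3 max filter per pass, zero padding beyond the image
    mask = ndimage.binary_dilation(mask, structure=selem,
                                   iterations=dilations, border_value=0)
    lumen = ndimage.binary_fill_holes(mask)
    eroded = ndimage.binary_erosion(lumen, structure=selem, border_value=0)
    border = lumen & ~eroded
    return lumen, border


def voronoi_cell_diameter(centroids: np.ndarray,
                          lumen: np.ndarray | None = None,
                          pixel_size: float = 1.0) -> np.ndarray:
    """Equivalent cell diameters 2 sqrt(A/pi) from the Voronoi tessellation
    of nucleus centroids (pixel coordinates).

    Cells with unbounded Voronoi regions (convex-hull points) are
    excluded; with a lumen mask, cells whose region leaves the lumen are
    excluded as well.  Degenerate inputs raise.
    """
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 4:
        raise ValueError("need >= 4 non-degenerate points")
    try:
        vor = Voronoi(pts)
    except QhullError as e:
        raise ValueError(f"degenerate centroid set: {e}") from e
    diameters = []
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 in region or len(region) == 0:
            continue  # unbounded
        poly = vor.vertices[region]
        if lumen is not None:
            ij = np.rint(poly).astype(int)
            h, w = lumen.shape
            inside = (ij[:, 0] >= 0) & (ij[:, 0] < h) & \
                     (ij[:, 1] >= 0) & (ij[:, 1] < w)
            if not inside.all() or not lumen[ij[inside][:, 0],
                                             ij[inside][:, 1]].all():
                continue
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        diameters.append(2.0 * np.sqrt(area / np.pi) * pixel_size)
    return np.asarray(diameters)


def border_distances(segmentation: SegmentationResult, border: np.ndarray,
                     pixel_size: float = 1.0) -> dict[int, float]:
    """Minimal distance (um) of each nucleus to the closest border pixel."""
    by, bx = np.nonzero(border)
    if len(by) == 0:
        raise ValueError("empty border")
    tree = cKDTree(np.stack([by, bx], axis=1))
    out = {}
    for p in segmentation.props:
        d, _ = tree.query(p.coords)
        out[p.label] = float(np.min(d) * pixel_size)
    return out


def radial_binning(distances: dict[int, float], values: dict[int, bool],
                   h: float = 1.0) -> pd.DataFrame:
    """Half-open binning of per-object flags by border distance.

    Bin i covers [h*i, h*(i+1)); returns per-bin counts and positive
    fractions.  Averaging across images is the arithmetic mean of the
    corresponding bins.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    labels = sorted(distances)
    d = np.array([distances[k] for k in labels], dtype=float)
    v = np.array([bool(values[k]) for k in labels], dtype=float)
    n_bins = int(np.floor(d.max() / h)) + 1 if len(d) else 0
    which = np.minimum((d // h).astype(int), max(n_bins - 1, 0))
    count = np.bincount(which, minlength=n_bins).astype(int)
    pos = np.bincount(which, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(count > 0, pos / np.maximum(count, 1), np.nan)
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "distance_lo": np.arange(n_bins) * h,
        "count": count,
        "count_positive": pos.astype(int),
        "fraction_positive": frac,
    })


def write_image(image: MultiChannelImage, path: str) -> None:
    """Write an RGB section as TIFF (float32) or PNG (8-bit)."""
    rgb = np.stack([image.red, image.green, image.blue], axis=-1)
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(p, rgb.astype(np.float32))
    else:
        import imageio.v3 as iio

        iio.imwrite(p, (rgb * 255).astype(np.uint8))


def read_image(path: str, pixel_size: float = 0.99) -> MultiChannelImage:
    """Read an RGB section image (TIFF or PNG) into [0, 1) channels."""
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = np.asarray(tifffile.imread(p), dtype=float)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(p), dtype=float)
    if arr.max() > 1:
        arr = arr / 256.0
    arr = np.clip(arr, 0.0, 1.0 - 1e-6)
    return MultiChannelImage(red=arr[..., 0], green=arr[..., 1],
                             blue=arr[..., 2], pixel_size=pixel_size)


# -- synthetic section generator ------------------------------------------


def generate_synthetic_section(
    n_nuclei: int = 60,
    shape: tuple[int, int] = (256, 256),
    nucleus_radius: float = 4.0,
    min_separation: float | None = None,
    positive_fraction: float = 0.5,
    noise: float = 0.0,
    background_gradient: float = 0.0,
    ecm_scale: float = 0.3,
    pixel_size: float = 0.99,
    seed: int = 0,
    max_tries: int = 20000,
) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render a synthetic stained cryosection with known ground truth.

    Nuclei are smooth Gaussian-profile blobs in the blue channel placed by
    sequential rejection sampling inside a central disc; marker-positive
    nuclei are bright in the red channel; the green channel carries a
    radially increasing ECM-like field.  Additive Gaussian noise and a
    linear background gradient are configurable.  Deterministic given the
    seed.  Returns the image and a nucleus table (y, x, positive flag).

    Raises if the requested density exceeds what rejection sampling can
    place (packing limit).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if min_separation is None:
        min_separation = 3.2 * nucleus_radius
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    disc_r = 0.42 * min(h, w)

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise ValueError("nucleus density above the packing limit of "
                             "the rejection sampler")
        r = disc_r * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        y, x = cy + r * np.sin(th), cx + r * np.cos(th)
        if all((y - yy) ** 2 + (x - xx) ** 2 >= min_separation ** 2
               for yy, xx in centers):
            centers.append((y, x))
    centers_arr = np.array(centers)
    positive = rng.uniform(size=n_nuclei) < positive_fraction

    yy, xx = np.mgrid[0:h, 0:w]
    blue = np.zeros(shape)
    red = np.zeros(shape)
    for (y, x), pos in zip(centers, positive):
        blob = 0.85 * np.exp(-((yy - y) ** 2 + (xx - x) ** 2)
                             / (2.0 * (nucleus_radius / 1.4) ** 2))
        blue = np.maximum(blue, blob)
        if pos:
            red = np.maximum(red, 0.9 * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2)
                / (2.0 * (nucleus_radius / 1.2) ** 2)))
    rad = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    green = ecm_scale * np.clip((disc_r - rad) / disc_r, 0.0, 1.0)

    def finalize(ch):
        ch = ch + background_gradient * (xx / max(w - 1, 1))
        if noise > 0:
            ch = ch + rng.normal(0.0, noise, size=shape)
        return np.clip(ch, 0.0, 1.0 - 1e-6)

    img = MultiChannelImage(red=finalize(red), green=finalize(green),
                            blue=finalize(blue), pixel_size=pixel_size)
    truth = pd.DataFrame({
        "y": centers_arr[:, 0],
        "x": centers_arr[:, 1],
        "positive": positive,
    })
    return img, truth


def match_nuclei_to_truth(segmentation: SegmentationResult,
                          truth: pd.DataFrame,
                          max_dist: float = 10.0) -> dict[int, bool]:
    """Gold-standard flags for segmented nuclei by nearest ground-truth
    center (for benchmarking classification)."""
    pts = truth[["y", "x"]].to_numpy()
    tree = cKDTree(pts)
    gold = {}
    for p in segmentation.props:
        d, j = tree.query(p.centroid)
        if d > max_dist:
            raise ValueError(f"nucleus {p.label} matches no ground-truth "
                             f"center within {max_dist} px")
        gold[p.label] = bool(truth["positive"].iloc[int(j)])
    return gold
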
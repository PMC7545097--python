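"""Fluorescence-image quantification: foci counting and N/C intensity ratio.

Re-implements the two ImageJ-plugin procedures used to score proximity
ligation assay (PLA) foci and GFP subcellular localization:

* foci: rolling-ball background removal on the signal channel, ImageJ-style
  Find Maxima (prominence / noise-tolerance semantics), and per-nucleus
  inside/outside counting against a DAPI nucleus mask;
* nuclei: background removal, Gaussian blur and Huang (PLA) or Otsu
  (confocal) thresholding, 8-connected components, hole filling, area
  filter;
* N/C ratio: mean background-removed GFP over each nucleus divided by the
  mean over a matched cytoplasmic region (hand-drawn masks or an automatic
  dilation ring).

All rasters are 2-D ``(row, col)`` arrays with finite, non-negative
intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima

__all__ = [
    "ImageField",
    "NucleusMask",
    "FocusPoint",
    "NucleiConfig",
    "rolling_ball_background",
    "gaussian_blur",
    "threshold_otsu",
    "threshold_huang",
    "find_maxima",
    "segment_nuclei",
    "count_foci",
    "nc_ratio",
    "normalize_ratios",
    "cytoplasm_rings",
]

_EIGHT = np.ones((3, 3), dtype=bool)


class DegenerateImageError(ValueError):
    """Raised when an operation needs at least two distinct intensities."""


@dataclass
class ImageField:
    """Named co-registered channels (e.g. ``dapi``, ``red``, ``gfp``)."""

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            ch = np.asarray(ch)
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
            self.channels[name] = ch

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_tiff(self, path, order: Sequence[str] | None = None) -> None:
        import tifffile

        names = list(order or self.channels)
        stack = np.stack([self.channels[n] for n in names])
        tifffile.imwrite(path, stack, metadata={"channels": names})

    @classmethod
    def from_tiff(cls, path, names: Sequence[str]) -> "ImageField":
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if len(names) != stack.shape[0]:
            raise ValueError("channel name count does not match TIFF planes")
        return cls({n: stack[i] for i, n in enumerate(names)})


@dataclass
class NucleusMask:
    """Label raster (0 = background, k = nucleus k) with per-nucleus stats."""

    labels: np.ndarray
    areas: dict[int, int]
    centroids: dict[int, tuple[float, float]]

    @property
    def n_nuclei(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class FocusPoint:
    """An accepted intensity maximum."""

    row: int
    col: int
    value: float
    inside_nucleus: int = 0


# ---------------------------------------------------------------------------
# Background removal and smoothing

def _ball_kernel(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= radius**2
    heights = np.zeros(footprint.shape)
    heights[footprint] = np.sqrt(radius**2 - d2[footprint])
    return heights, footprint


def rolling_ball_background(
    image: np.ndarray, radius: float, downscale_above: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate a smooth background by rolling a ball under the intensity surface.

    The background is the grayscale morphological opening of the image with
    a non-flat ball structuring element of the given radius (the rolling-ball
    definition): it lies at or below the image everywhere, so the corrected
    image ``image − background`` is non-negative, and a constant image
    corrects to all zeros. For radii above ``downscale_above`` the image is
    block-minimum downscaled before the opening and the background is
    bilinearly upscaled (the classic large-radius speedup); the background
    is clipped to stay below the image.

    Returns ``(background, corrected)``.
    """
    img = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape):
        warnings.warn("rolling-ball radius exceeds image size; using global "
                      "minimum as background", stacklevel=2)
        background = np.full_like(img, img.min())
        return background, img - background

    shrink = max(1, int(radius) // downscale_above)
    if shrink == 1:
        background = np.minimum(_ball_opening(img, radius), img)
    else:
        pad_r = (-img.shape[0]) % shrink
        pad_c = (-img.shape[1]) % shrink
        padded = np.pad(img, ((0, pad_r), (0, pad_c)), mode="edge")
        small = padded.reshape(
            padded.shape[0] // shrink, shrink, padded.shape[1] // shrink, shrink
        ).min(axis=(1, 3))
        small_bg = _ball_opening(small, radius / shrink)
        background = ndi.zoom(small_bg, shrink, order=1)[: img.shape[0], : img.shape[1]]
        background = np.minimum(background, img)
    return background, img - background


def _ball_opening(img: np.ndarray, radius: float) -> np.ndarray:
    heights, footprint = _ball_kernel(radius)
    structure = np.where(footprint, heights, 0.0)
    eroded = ndi.grey_erosion(img, structure=structure, footprint=footprint,
                              mode="nearest")
    return ndi.grey_dilation(eroded, structure=structure, footprint=footprint,
                             mode="nearest")


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective padding; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(image, dtype=float)
    if sigma == 0:
        return img.copy()
    return ndi.gaussian_filter(img, sigma=sigma, mode="reflect")


# ---------------------------------------------------------------------------
# Histogram thresholds

def _histogram(image: np.ndarray, nbins: int) -> tuple[np.ndarray, np.ndarray]:
    """(levels, counts). Integer images use one bin per integer level so the
    threshold candidates are the actual gray levels; float images use
    ``nbins`` equal-width bins with bin-center levels."""
    img = np.asarray(image)
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        raise DegenerateImageError("image has a single intensity value")
    if np.issubdtype(img.dtype, np.integer) and (vmax - vmin) < 65536:
        lo = int(vmin)
        counts = np.bincount((img.ravel() - lo).astype(np.int64))
        levels = np.arange(lo, lo + counts.size, dtype=float)
    else:
        counts, edges = np.histogram(img.ravel(), bins=nbins, range=(vmin, vmax))
        levels = (edges[:-1] + edges[1:]) / 2
    return levels, counts.astype(float)


def threshold_otsu(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximizes the between-class variance of the split
    ``g <= t`` / ``g > t`` over the intensity histogram. Ties resolve to the
    lowest candidate."""
    levels, counts = _histogram(image, nbins)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    between = between[:-1]  # both classes must be non-empty
    return float(levels[int(np.argmax(between))])


def threshold_huang(image: np.ndarray, nbins: int = 256) -> float:
    """Huang–Wang fuzzy-entropy threshold.

    For each candidate t the membership of gray level g to its class (below
    or above t) is ``u(g) = 1 / (1 + |g − mu_class| / C)`` with
    ``C = g_max − g_min``; the cost is the Shannon fuzzy entropy
    ``sum_g h(g) * S(u(g))`` with ``S(u) = −u ln u − (1−u) ln(1−u)``.
    Returns the candidate minimizing the cost (ties to the lowest).
    """
    levels, counts = _histogram(image, nbins)
    C = levels[-1] - levels[0]
    w = np.cumsum(counts)
    m = np.cumsum(counts * levels)
    total_w, total_m = w[-1], m[-1]
    best_t, best_cost = None, np.inf
    for i in range(levels.size - 1):  # split after level i; both classes non-empty
        if w[i] == 0 or w[i] == total_w:
            continue
        mu0 = m[i] / w[i]
        mu1 = (total_m - m[i]) / (total_w - w[i])
        mu = np.where(np.arange(levels.size) <= i, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(levels - mu) / C)
        cost = float(np.sum(counts * _fuzzy_entropy(u)))
        if cost < best_cost - 1e-12:
            best_cost, best_t = cost, levels[i]
    if best_t is None:
        raise DegenerateImageError("no valid threshold candidate")
    return float(best_t)


def _fuzzy_entropy(u: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -u * np.log(u) - (1 - u) * np.log(1 - u)
    return np.where((u <= 0) | (u >= 1), 0.0, s)


# ---------------------------------------------------------------------------
# Find Maxima (prominence semantics)

def find_maxima(image: np.ndarray, noise_tolerance: float) -> list[FocusPoint]:
    """ImageJ-style Find Maxima with noise-tolerance (prominence) semantics.

    A regional maximum of value v is accepted iff every path from it to any
    strictly higher pixel first descends below ``v − noise_tolerance``
    (8-connectivity). Equal-valued plateaus are merged to a single point:
    the plateau pixel closest to the plateau's center of mass, ties broken
    by smallest row then column. A flat image yields no maxima.

    Implemented as a descending-level union-find sweep: components of
    pixels with value above the current level are merged as the level
    drops; a candidate maximum is killed when its component acquires a
    strictly higher pixel while the level is still within the tolerance
    band, and accepted once the level falls below ``v − tolerance``.
    """
    if noise_tolerance <= 0:
        raise ValueError("noise_tolerance must be positive")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    flat = img.ravel()
    if flat.size == 0 or flat.min() == flat.max():
        return []

    cand = local_maxima(img, connectivity=2, allow_borders=True)
    plateau_labels, n_plateaus = ndi.label(cand, structure=_EIGHT)
    plab = plateau_labels.ravel()
    peak_value = np.zeros(n_plateaus + 1)
    anchors = np.full(n_plateaus + 1, -1, dtype=np.int64)
    for p in np.flatnonzero(plab):
        pid = plab[p]
        peak_value[pid] = flat[p]
        if anchors[pid] == -1 or p < anchors[pid]:
            anchors[pid] = p

    order = np.argsort(flat, kind="stable")[::-1]
    parent = np.full(flat.size, -1, dtype=np.int64)
    comp_max: dict[int, float] = {}
    live: dict[int, list[int]] = {}
    accepted: list[int] = []
    tol = float(noise_tolerance)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(a: int, b: int, level: float) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if len(live.get(ra, ())) < len(live.get(rb, ())):
            ra, rb = rb, ra
        merged_max = max(comp_max[ra], comp_max[rb])
        keep = []
        for pid in live.pop(ra, []) + live.pop(rb, []):
            vp = peak_value[pid]
            if vp >= merged_max:
                keep.append(pid)
            elif level < vp - tol:
                accepted.append(pid)
            # else: a strictly higher pixel is reachable within tolerance -> killed
        parent[rb] = ra
        comp_max[ra] = merged_max
        live[ra] = keep

    vals = flat[order]
    i, n = 0, flat.size
    level_plateaus: dict[float, list[int]] = {}
    for pid in range(1, n_plateaus + 1):
        level_plateaus.setdefault(peak_value[pid], []).append(pid)
    while i < n:
        v = vals[i]
        j = i
        while j < n and vals[j] == v:
            j += 1
        for p in order[i:j]:
            parent[p] = p
            comp_max[p] = v
            live[p] = []
            r, c = divmod(int(p), w)
            for dr in (-1, 0, 1):
                rr = r + dr
                if not 0 <= rr < h:
                    continue
                for dc in (-1, 0, 1):
                    cc = c + dc
                    if (dr or dc) and 0 <= cc < w:
                        q = rr * w + cc
                        if parent[q] != -1:
                            union(p, q, v)
        for pid in level_plateaus.get(v, ()):
            root = find(int(anchors[pid]))
            if comp_max[root] <= peak_value[pid]:
                live[root].append(pid)
        i = j
    for peaks in live.values():
        accepted.extend(peaks)

    points = []
    for pid in accepted:
        rows, cols = np.nonzero(plateau_labels == pid)
        com_r, com_c = rows.mean(), cols.mean()
        d2 = (rows - com_r) ** 2 + (cols - com_c) ** 2
        best = sorted(zip(d2, rows, cols))[0]
        points.append(FocusPoint(row=int(best[1]), col=int(best[2]),
                                 value=float(peak_value[pid])))
    points.sort(key=lambda pt: (pt.row, pt.col))
    return points


# ---------------------------------------------------------------------------
# Nucleus segmentation and counting

@dataclass(frozen=True)
class NucleiConfig:
    """Nucleus-detection parameters (pixel units)."""

    rolling_radius: float = 50.0
    sigma: float = 2.0
    method: str = "huang"
    min_area: int = 200
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("huang", "otsu"):
            raise ValueError("method must be 'huang' or 'otsu'")


def segment_nuclei(dapi: np.ndarray, cfg: NucleiConfig = NucleiConfig()) -> NucleusMask:
    """Detect nuclei on the DAPI channel.

    Pipeline: rolling-ball background removal, Gaussian blur, Huang or Otsu
    threshold (foreground strictly above threshold), 8-connected labelling,
    hole filling and minimum-area filtering. Labels are renumbered 1..n in
    raster order and are stable for a fixed input.
    """
    _, corrected = rolling_ball_background(dapi, cfg.rolling_radius)
    blurred = gaussian_blur(corrected, cfg.sigma)
    span = float(blurred.max() - blurred.min())
    if span <= 1e-9 * max(1.0, abs(float(blurred.max()))):
        warnings.warn("blank field: no nuclei found", stacklevel=2)
        return NucleusMask(np.zeros(dapi.shape, dtype=np.int32), {}, {})
    try:
        if cfg.method == "huang":
            t = threshold_huang(blurred)
        else:
            t = threshold_otsu(blurred)
    except DegenerateImageError:
        warnings.warn("blank field: no nuclei found", stacklevel=2)
        return NucleusMask(np.zeros(dapi.shape, dtype=np.int32), {}, {})
    mask = blurred > t
    if cfg.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=_EIGHT)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = [k + 1 for k, a in enumerate(areas) if a >= cfg.min_area]
    if not keep:
        warnings.warn("no nucleus passed the area filter", stacklevel=2)
        return NucleusMask(np.zeros(dapi.shape, dtype=np.int32), {}, {})
    out = np.zeros_like(labels, dtype=np.int32)
    areas_out: dict[int, int] = {}
    centroids: dict[int, tuple[float, float]] = {}
    for new, old in enumerate(keep, start=1):
        sel = labels == old
        out[sel] = new
        areas_out[new] = int(sel.sum())
        rows, cols = np.nonzero(sel)
        centroids[new] = (float(rows.mean()), float(cols.mean()))
    return NucleusMask(out, areas_out, centroids)


def count_foci(
    foci: Iterable[FocusPoint], mask: NucleusMask
) -> tuple[int, int, dict[int, int]]:
    """Partition foci into nuclear and cytoplasmic by mask membership.

    Returns ``(n_nuclear, n_cytoplasmic, per_nucleus_counts)``; the two
    totals always sum to the number of foci.
    """
    per_nucleus = {k: 0 for k in mask.areas}
    n_nuclear = n_cyto = 0
    for pt in foci:
        label = int(mask.labels[pt.row, pt.col])
        if label > 0:
            n_nuclear += 1
            per_nucleus[label] = per_nucleus.get(label, 0) + 1
        else:
            n_cyto += 1
    return n_nuclear, n_cyto, per_nucleus


def assign_foci(foci: Iterable[FocusPoint], mask: NucleusMask) -> list[FocusPoint]:
    """Copy of the foci with ``inside_nucleus`` set from the mask."""
    return [
        FocusPoint(pt.row, pt.col, pt.value,
                   inside_nucleus=int(mask.labels[pt.row, pt.col]))
        for pt in foci
    ]


# ---------------------------------------------------------------------------
# Nuclear / cytoplasmic ratio

def cytoplasm_rings(mask: NucleusMask, width: int = 8) -> dict[int, np.ndarray]:
    """Automatic cytoplasm regions: a dilation ring around each nucleus,
    excluding every nucleus. A substitute for hand-drawn regions."""
    all_nuclei = mask.labels > 0
    rings: dict[int, np.ndarray] = {}
    for label in mask.areas:
        nucleus = mask.labels == label
        dilated = ndi.binary_dilation(nucleus, structure=_EIGHT, iterations=width)
        rings[label] = dilated & ~all_nuclei
    return rings


def nc_ratio(
    field: ImageField,
    mask: NucleusMask,
    cytoplasm: Mapping[int, np.ndarray] | None = None,
    channel: str = "gfp",
    rolling_radius: float | None = None,
    ring_width: int = 8,
) -> dict[int, float]:
    """Nuclear/cytoplasmic mean-intensity ratio per cell.

    For each nucleus, the ratio of the mean (optionally background-removed)
    signal over the nucleus to the mean over its cytoplasm region
    (hand-drawn masks via ``cytoplasm``, else an automatic dilation ring).
    """
    signal = np.asarray(field[channel], dtype=float)
    if rolling_radius is not None:
        _, signal = rolling_ball_background(signal, rolling_radius)
    if cytoplasm is None:
        cytoplasm = cytoplasm_rings(mask, width=ring_width)
    ratios: dict[int, float] = {}
    for label in mask.areas:
        region = cytoplasm.get(label)
        if region is None or not region.any():
            raise ValueError(f"empty cytoplasm region for nucleus {label}")
        cyto_mean = float(signal[region].mean())
        if cyto_mean == 0:
            raise ValueError(f"zero cytoplasmic mean for nucleus {label}")
        nuc_mean = float(signal[mask.labels == label].mean())
        ratios[label] = nuc_mean / cyto_mean
    return ratios


def normalize_ratios(
    ratios: Mapping[int, float],
    reference: Mapping[int, float] | Sequence[float],
    stat: str = "median",
) -> dict[int, float]:
    """Divide per-cell ratios by the reference condition's median (or mean),
    so the reference (e.g. wild-type) condition centers at 1."""
    values = np.asarray(
        list(reference.values()) if isinstance(reference, Mapping) else reference,
        dtype=float,
    )
    if values.size == 0:
        raise ValueError("empty reference condition")
    denom = float(np.median(values) if stat == "median" else values.mean())
    if denom == 0:
        raise ValueError("reference statistic is zero")
    return {k: v / denom for k, v in ratios.items()}
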
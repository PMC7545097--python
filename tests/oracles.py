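"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written as a direct transcription of the defining
property (exhaustive search, per-pixel loops, explicit set operations) and
deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


# --- digestion ------------------------------------------------------------

def digest_zero_missed(sequence: str, enzymes, proline_block=True,
                       gluc_cleaves_d=False, blocked=frozenset()):
    """Fully cleaved peptides by scanning every bond against the rules."""
    cuts = []
    for i in range(1, len(sequence)):
        if i in blocked:
            continue
        aa, nxt = sequence[i - 1], sequence[i]
        if "trypsin" in enzymes and aa in "KR" and not (proline_block and nxt == "P"):
            cuts.append(i)
        elif "gluc" in enzymes and (aa == "E" or (gluc_cleaves_d and aa == "D")):
            cuts.append(i)
    bounds = [0] + cuts + [len(sequence)]
    return [sequence[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]


def merged_peptides(base: list[str], max_missed: int) -> set[tuple[str, int]]:
    """All merges of <= max_missed+1 adjacent fully-cleaved peptides."""
    out = set()
    for i in range(len(base)):
        for k in range(max_missed + 1):
            if i + k < len(base):
                out.add(("".join(base[i:i + k + 1]), k))
    return out


# --- heptad ----------------------------------------------------------------

def cycle_letters(start: int, phase: str, position: int) -> str:
    """Walk the a..g cycle one residue at a time from (start, phase)."""
    letters = "abcdefg"
    idx = letters.index(phase)
    p = start
    while p < position:
        p += 1
        idx = (idx + 1) % 7
    return letters[idx]


# --- statistics ------------------------------------------------------------

def longest_consecutive(values) -> int:
    vals = sorted(set(values))
    best = 0
    for v in vals:
        if v - 1 in vals:
            continue
        run = 1
        while v + run in vals:
            run += 1
        best = max(best, run)
    return best


def pooled_t_p_less(x, y) -> float:
    """One-tailed pooled-variance p from the closed-form t CDF (mpmath-free:
    regularized incomplete beta via scipy.special)."""
    from scipy.special import betainc

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    dof = nx + ny - 2
    sp2 = (sum((x - x.mean()) ** 2) + sum((y - y.mean()) ** 2)) / dof
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    # P(T <= t) for Student t via the incomplete beta function
    ib = betainc(dof / 2, 0.5, dof / (dof + t * t)) / 2
    return float(ib if t < 0 else 1 - ib)


# --- imaging ---------------------------------------------------------------

def brute_ball_opening(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a non-flat ball element, per-pixel loops."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = yy**2 + xx**2 <= radius**2
    heights = np.zeros_like(yy, dtype=float)
    heights[inside] = np.sqrt(radius**2 - (yy**2 + xx**2)[inside])
    padded = np.pad(img.astype(float), r, mode="edge")
    h, w = img.shape
    eroded = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            window = padded[i:i + 2 * r + 1, j:j + 2 * r + 1]
            eroded[i, j] = np.min(window[inside] - heights[inside])
    padded = np.pad(eroded, r, mode="edge")
    opened = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            window = padded[i:i + 2 * r + 1, j:j + 2 * r + 1]
            opened[i, j] = np.max(window[inside] + heights[inside])
    return opened


def brute_otsu(img: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over every gray level,
    classes computed by direct pixel comparison."""
    flat = img.ravel().astype(float)
    best_t, best_var = None, -np.inf
    for t in range(int(flat.min()), int(flat.max())):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size, hi.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def brute_huang(img: np.ndarray) -> int:
    """Exhaustive fuzzy-entropy minimization by direct pixel membership."""
    flat = img.ravel().astype(float)
    C = flat.max() - flat.min()
    best_t, best_cost = None, np.inf
    for t in range(int(flat.min()), int(flat.max())):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        mu = np.where(flat <= t, lo.mean(), hi.mean())
        u = 1.0 / (1.0 + np.abs(flat - mu) / C)
        inner = (u > 0) & (u < 1)
        ui = u[inner]
        cost = float(np.sum(-ui * np.log(ui) - (1 - ui) * np.log(1 - ui)))
        if cost < best_cost - 1e-12:
            best_cost, best_t = cost, t
    return best_t


def brute_prominent_maxima(img: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Accepted maxima by direct application of the prominence definition.

    For every equal-valued plateau that is a regional maximum, build the
    mask of pixels >= value - tol, label it (8-connectivity) and reject the
    plateau iff its component contains a strictly higher pixel. Accepted
    plateaus report the pixel nearest their center of mass (ties by row,
    then column).
    """
    img = img.astype(float)
    eight = np.ones((3, 3), bool)
    points = []
    # a pixel with no strictly higher neighbour satisfies img == dilation
    no_higher_neighbor = img == ndi.grey_dilation(img, footprint=eight)
    for v in np.unique(img):
        same, n = ndi.label(img == v, structure=eight)
        reach, _ = ndi.label(img >= v - tol, structure=eight)
        for lab in range(1, n + 1):
            plateau = same == lab
            if not np.all(no_higher_neighbor[plateau]):
                continue  # not a regional maximum
            comp = reach == reach[plateau][0]
            if np.max(img[comp]) > v:
                continue  # a higher summit is reachable within tolerance
            rows, cols = np.nonzero(plateau)
            com_r, com_c = rows.mean(), cols.mean()
            d2 = (rows - com_r) ** 2 + (cols - com_c) ** 2
            _, r, c = sorted(zip(d2, rows, cols))[0]
            points.append((int(r), int(c)))
    return sorted(points)
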
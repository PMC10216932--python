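"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity from its mathematical set
definition, deliberately avoiding the library routines the package itself
uses, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dilate_bruteforce(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Set-definition dilation: union of the mask translated by every
    footprint offset (offsets relative to the footprint centre); pixels
    pushed beyond the frame are dropped (outside = background)."""
    out = np.zeros_like(mask, dtype=bool)
    cr, cc = (footprint.shape[0] - 1) // 2, (footprint.shape[1] - 1) // 2
    nr, nc = mask.shape
    for fr, fc in zip(*np.nonzero(footprint)):
        dr, dc = fr - cr, fc - cc
        for r, c in zip(*np.nonzero(mask)):
            rr, cc2 = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc2 < nc:
                out[rr, cc2] = True
    return out


def erode_bruteforce(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Set-definition erosion with outside-the-frame counted as foreground
    (so closing built from this pair is extensive on the finite grid)."""
    out = np.zeros_like(mask, dtype=bool)
    cr, cc = (footprint.shape[0] - 1) // 2, (footprint.shape[1] - 1) // 2
    nr, nc = mask.shape
    offs = [(fr - cr, fc - cc) for fr, fc in zip(*np.nonzero(footprint))]
    for r in range(nr):
        for c in range(nc):
            ok = True
            for dr, dc in offs:
                rr, cc2 = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc2 < nc and not mask[rr, cc2]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def close_bruteforce(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return erode_bruteforce(dilate_bruteforce(mask, footprint), footprint)


def minimal_enclosing_circle_bruteforce(points: np.ndarray) -> float:
    """Exact smallest enclosing circle radius by enumerating every circle
    determined by a pair (diameter) or triple (circumcircle) of points.

    The optimal circle always passes through 2 or 3 of the points, so the
    smallest enumerated circle containing all points is exact.  The
    enumeration is vectorised but follows the definition directly.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 1:
        return 0.0
    centers = []
    radii = []
    # pairs: diameter circles
    ii, jj = np.triu_indices(n, k=1)
    c2 = (pts[ii] + pts[jj]) / 2.0
    r2 = np.linalg.norm(pts[ii] - c2, axis=1)
    centers.append(c2)
    radii.append(r2)
    # triples: circumcircles
    if n >= 3:
        tri = np.array(list(itertools.combinations(range(n), 3)))
        a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
        d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) +
                   b[:, 0] * (c[:, 1] - a[:, 1]) +
                   c[:, 0] * (a[:, 1] - b[:, 1]))
        ok = np.abs(d) > 1e-12
        a, b, c, d = a[ok], b[ok], c[ok], d[ok]
        a2 = (a ** 2).sum(axis=1)
        b2 = (b ** 2).sum(axis=1)
        c2s = (c ** 2).sum(axis=1)
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) +
              c2s * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) +
              c2s * (b[:, 0] - a[:, 0])) / d
        c3 = np.stack([ux, uy], axis=1)
        r3 = np.linalg.norm(a - c3, axis=1)
        centers.append(c3)
        radii.append(r3)
    centers = np.concatenate(centers)
    radii = np.concatenate(radii)
    # containment: max distance from each candidate centre to any point
    dists = np.linalg.norm(pts[None, :, :] - centers[:, None, :], axis=2)
    contains = dists.max(axis=1) <= radii + 1e-9
    return float(radii[contains].min())


def inscribed_radius_bruteforce(mask: np.ndarray) -> float:
    """Largest inscribed circle via exhaustive centre search: for every
    foreground pixel centre, the nearest background pixel centre distance;
    the maximum over centres is the inscribed radius."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        raise ValueError("mask has no background")
    d = np.sqrt(((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).max())


def feret_extents_fine_sweep(points: np.ndarray,
                             step_deg: float = 0.1) -> tuple[float, float]:
    """Caliper widths by a fine rotation sweep over the given points."""
    pts = np.asarray(points, dtype=float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), float(widths.max())


def chi2_2x2_bruteforce(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table from the closed form
    n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)), p from the chi2(1) survival
    function computed as erfc(sqrt(x/2))."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = math.erfc(math.sqrt(stat / 2.0))
    return float(stat), float(p)


def pooled_t_power(delta_sd: float, n1: int, n2: int,
                   alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided pooled t-test for a true mean
    difference of ``delta_sd`` standard deviations, via the noncentral t."""
    from scipy import stats
    df = n1 + n2 - 2
    nc = delta_sd / math.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc)
                 + stats.nct.cdf(-tcrit, df, nc))


def random_blob(rng: np.random.Generator, size: int = 16,
                sigma: float = 2.0) -> np.ndarray:
    """Random smooth blob mask (thresholded filtered noise), never empty."""
    from scipy import ndimage as ndi
    field = ndi.gaussian_filter(rng.normal(size=(size, size)), sigma)
    mask = field > np.quantile(field, rng.uniform(0.55, 0.85))
    if not mask.any():
        mask[size // 2, size // 2] = True
    return mask
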
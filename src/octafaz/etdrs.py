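"""Vessel and perfusion density over the ETDRS macular grid.

The ETDRS grid partitions the macula into 9 subfields: a 1-mm central
disk (subfield 1), an inner annulus (0.5–1.5 mm radius) split into
temporal / superior / nasal / inferior quadrants by the 45° diagonals
(subfields 2–5), and an outer annulus (1.5–3.0 mm radius) split likewise
(subfields 6–9).  Ring summaries are unweighted means of the member
subfield values: central = {1}, inner = {2..5}, outer = {6..9},
full = {1..9}.

Perfusion density (PD) is the percentage of a subfield's area covered by
binarised vessel pixels; vessel density (VD) is the skeletonised vessel
length per unit area (mm per mm²), the length-based metric whose
magnitudes (~15 mm⁻¹) are printed alongside PD (~37%) on commercial
angiography reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vessels import skeleton_length_map

RING_DIAMETERS_MM = (1.0, 3.0, 6.0)
SUBFIELD_NAMES = {
    1: "center", 2: "inner_temporal", 3: "inner_superior",
    4: "inner_nasal", 5: "inner_inferior", 6: "outer_temporal",
    7: "outer_superior", 8: "outer_nasal", 9: "outer_inferior",
}
RING_MEMBERS = {
    "central": (1,),
    "inner": (2, 3, 4, 5),
    "outer": (6, 7, 8, 9),
    "full": tuple(range(1, 10)),
}


@dataclass(frozen=True)
class EtdrsGrid:
    """Per-pixel subfield labels (1–9, 0 = outside the 6-mm grid)."""

    labels: np.ndarray
    center_px: tuple[int, int]
    scale: float
    laterality: str = "OD"


@dataclass(frozen=True)
class RingDensities:
    """Ring-aggregated vessel density (mm⁻¹) and perfusion density (%)."""

    vd_central: float
    vd_inner: float
    vd_outer: float
    vd_full: float
    pd_central: float
    pd_inner: float
    pd_outer: float
    pd_full: float


def build_etdrs_grid(image_shape: tuple[int, int],
                     scale: float,
                     center_px: tuple[int, int] | None = None,
                     laterality: str = "OD") -> EtdrsGrid:
    """Label every pixel with its ETDRS subfield.

    Radius bands (0–0.5, 0.5–1.5, 1.5–3.0 mm) come from the standard
    1/3/6-mm ring diameters; quadrants are bounded by the 45° diagonals.
    ``laterality`` fixes which horizontal quadrant is called temporal
    (convention here: temporal is the image-left quadrant for OD, mirrored
    for OS); it renames quadrants but never changes ring values.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")
    nr, nc = image_shape
    if center_px is None:
        center_px = (nr // 2, nc // 2)
    cr, cc = center_px
    r_out = RING_DIAMETERS_MM[2] / 2.0 / scale
    # 1-px slack: a 6-mm grid legitimately spans a 6-mm image exactly
    if (cr - r_out < -1 or cc - r_out < -1 or
            cr + r_out > nr or cc + r_out > nc):
        raise ValueError("6-mm outer ring does not fit inside the image")

    rr, cc_grid = np.mgrid[0:nr, 0:nc]
    dy = rr - cr          # grows downward (inferior)
    dx = cc_grid - cc     # grows rightward
    r_mm = np.hypot(dy, dx) * scale

    ang = np.degrees(np.arctan2(-dy, dx))  # CCW from image-right, (-180,180]
    superior = (ang >= 45.0) & (ang < 135.0)
    inferior = (ang >= -135.0) & (ang < -45.0)
    right = (ang >= -45.0) & (ang < 45.0)
    left = ~(superior | inferior | right)
    temporal, nasal = (left, right) if laterality == "OD" else (right, left)

    labels = np.zeros(image_shape, dtype=np.uint8)
    labels[r_mm <= 0.5] = 1
    inner = (r_mm > 0.5) & (r_mm <= 1.5)
    outer = (r_mm > 1.5) & (r_mm <= 3.0)
    for band, offset in ((inner, 2), (outer, 6)):
        labels[band & temporal] = offset
        labels[band & superior] = offset + 1
        labels[band & nasal] = offset + 2
        labels[band & inferior] = offset + 3
    return EtdrsGrid(labels=labels, center_px=center_px, scale=scale,
                     laterality=laterality)


def subfield_perfusion_density(vessel_mask: np.ndarray,
                               grid: EtdrsGrid) -> dict[int, float]:
    """Percent of each subfield's pixels covered by vessel mask."""
    mask = np.asarray(vessel_mask, dtype=bool)
    if mask.shape != grid.labels.shape:
        raise ValueError("mask and grid shapes differ")
    out = {}
    for k in range(1, 10):
        sel = grid.labels == k
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"subfield {k} is empty")
        out[k] = 100.0 * float(mask[sel].sum()) / n
    return out


def subfield_vessel_density(skeleton: np.ndarray,
                            grid: EtdrsGrid) -> dict[int, float]:
    """Weighted skeleton length (mm) per subfield area (mm²)."""
    if np.asarray(skeleton).shape != grid.labels.shape:
        raise ValueError("skeleton and grid shapes differ")
    lmap = skeleton_length_map(skeleton)
    s = grid.scale
    out = {}
    for k in range(1, 10):
        sel = grid.labels == k
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"subfield {k} is empty")
        out[k] = (float(lmap[sel].sum()) * s) / (n * s * s)
    return out


def _ring_mean(values: dict[int, float], ring: str) -> float:
    if ring not in RING_MEMBERS:
        raise ValueError(f"unknown ring {ring!r}")
    members = RING_MEMBERS[ring]
    return float(np.mean([values[k] for k in members]))


def ring_perfusion_density(vessel_mask: np.ndarray, grid: EtdrsGrid,
                           ring: str) -> float:
    """Unweighted mean of the member subfields' perfusion densities (%)."""
    return _ring_mean(subfield_perfusion_density(vessel_mask, grid), ring)


def ring_vessel_density(skeleton: np.ndarray, grid: EtdrsGrid,
                        ring: str) -> float:
    """Unweighted mean of the member subfields' vessel densities (mm⁻¹)."""
    return _ring_mean(subfield_vessel_density(skeleton, grid), ring)


def compute_ring_densities(vessel_mask: np.ndarray, skeleton: np.ndarray,
                           grid: EtdrsGrid) -> RingDensities:
    pd = subfield_perfusion_density(vessel_mask, grid)
    vd = subfield_vessel_density(skeleton, grid)
    return RingDensities(
        vd_central=_ring_mean(vd, "central"),
        vd_inner=_ring_mean(vd, "inner"),
        vd_outer=_ring_mean(vd, "outer"),
        vd_full=_ring_mean(vd, "full"),
        pd_central=_ring_mean(pd, "central"),
        pd_inner=_ring_mean(pd, "inner"),
        pd_outer=_ring_mean(pd, "outer"),
        pd_full=_ring_mean(pd, "full"),
    )
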
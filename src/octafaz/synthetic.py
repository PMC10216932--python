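"""Synthetic en-face OCTA phantoms and cohorts with known ground truth.

No public OCTA dataset accompanies the clinical problem this package
addresses, so every downstream stage is validated against phantoms: an
en-face angiogram is emulated as bright curvilinear vessel strokes on a
mid-grey background, with a dark avascular blob (the FAZ) of exactly known
geometry, plus additive Gaussian noise.  Cohorts are emulated as per-eye
records whose responder / non-responder groups differ by planted effects
in central subfield thickness (CST) change and in the OCTA metrics.

The generator is deterministic: equal seeds give bit-identical images and
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EnFaceImage

# Study conditions emulated by default: a 6 mm x 6 mm field sampled at
# 420 x 420 px, and a 61-eye cohort splitting 30/31 under the quartile rule.
DEFAULT_FIELD_MM = 6.0
DEFAULT_IMAGE_SIZE = 420
DEFAULT_SCALE = DEFAULT_FIELD_MM / DEFAULT_IMAGE_SIZE

FAZ_LEVEL = 30.0
BACKGROUND_LEVEL = 100.0
VESSEL_LEVEL = 200.0  # FAZ-to-vessel contrast 170 >= the 60-level floor


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom angiogram.

    faz_shape : {"disk", "ellipse", "blob"}
        Geometry of the avascular region.  ``radius_mm`` sizes the disk and
        the blob's base circle; ``semi_axes_mm`` (a, b), a >= b, sizes the
        ellipse.
    acircularity : float in [0, 1)
        Amplitude of the radial Fourier perturbation applied to the blob
        boundary; 0 leaves a circle.
    vessel_fraction : float in [0, 1]
        Target areal fraction of the frame covered by vessel strokes.
    vessel_width_px : float
        Mean stroke width in pixels.
    noise_sd : float
        SD of additive Gaussian noise in gray levels.
    max_gap_px : int
        Largest avascular gap (in pixels) tolerated in the vessel mesh
        away from the FAZ.  In a perifoveal capillary plexus every
        avascular gap other than the FAZ is far smaller than the FAZ;
        residual voids above this size are filled with extra strokes.
        Set to 0 to disable gap capping.
    """

    faz_shape: str = "disk"
    radius_mm: float = 0.35
    semi_axes_mm: tuple[float, float] | None = None
    acircularity: float = 0.0
    vessel_fraction: float = 0.45
    vessel_width_px: float = 2.0
    noise_sd: float = 8.0
    image_size: int = DEFAULT_IMAGE_SIZE
    scale: float = DEFAULT_SCALE
    max_gap_px: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.faz_shape not in ("disk", "ellipse", "blob"):
            raise ValueError(f"unknown faz_shape {self.faz_shape!r}")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not 0.0 <= self.vessel_fraction <= 1.0:
            raise ValueError("vessel_fraction must lie in [0, 1]")
        if not 0.0 <= self.acircularity < 1.0:
            raise ValueError("acircularity must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.faz_shape == "ellipse":
            if self.semi_axes_mm is None:
                raise ValueError("ellipse requires semi_axes_mm")
            a, b = self.semi_axes_mm
            if not (a >= b > 0):
                raise ValueError("semi_axes_mm must satisfy a >= b > 0")

    def max_radius_px(self) -> float:
        if self.faz_shape == "ellipse":
            r_mm = max(self.semi_axes_mm)
        else:
            r_mm = self.radius_mm * (1.0 + self.acircularity)
        return r_mm / self.scale


@dataclass
class PhantomTruth:
    """Exact generative ground truth for one phantom.

    ``true_area`` equals the FAZ mask pixel count times scale² by
    construction; vessel area likewise counts visible vessel pixels.
    ``true_vessel_length`` is the drawn centreline length in mm.
    """

    faz_mask: np.ndarray
    true_area: float
    true_eccentricity: float
    true_vessel_length: float
    true_vessel_area: float
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        self.faz_mask = np.asarray(self.faz_mask, dtype=bool)


# --------------------------------------------------------------------------
# FAZ geometry rasterisation


def _rasterize_faz(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Rasterise the generative FAZ shape; returns (mask, analytic ecc)."""
    n = spec.image_size
    if spec.max_radius_px() >= n / 2:
        raise ValueError("FAZ does not fit inside the field")
    c = (n - 1) / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    dy = rr - c
    dx = cc - c

    if spec.faz_shape == "disk":
        r_px = spec.radius_mm / spec.scale
        mask = dy * dy + dx * dx <= r_px * r_px
        ecc = 0.0
    elif spec.faz_shape == "ellipse":
        a_px = spec.semi_axes_mm[0] / spec.scale
        b_px = spec.semi_axes_mm[1] / spec.scale
        mask = (dx / a_px) ** 2 + (dy / b_px) ** 2 <= 1.0
        ecc = math.sqrt(1.0 - (b_px / a_px) ** 2)
    else:  # perturbed blob: radial Fourier modes k = 2..5
        rng = np.random.default_rng(spec.seed)
        k = np.arange(2, 6)
        coef = rng.uniform(0.3, 1.0, size=k.size)
        coef *= spec.acircularity / coef.sum()
        phase = rng.uniform(0.0, 2.0 * np.pi, size=k.size)
        theta = np.arctan2(dy, dx)
        r0 = spec.radius_mm / spec.scale
        r_theta = r0 * (1.0 + np.sum(
            coef[:, None, None] * np.cos(k[:, None, None] * theta[None] +
                                         phase[:, None, None]), axis=0))
        mask = np.hypot(dy, dx) <= r_theta
        ecc = _mask_eccentricity(mask)
    return mask, float(ecc)


def _mask_eccentricity(mask: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    mu20 = np.var(xs)
    mu02 = np.var(ys)
    mu11 = np.mean((xs - xs.mean()) * (ys - ys.mean()))
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11 ** 2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    if lam1 <= 0:
        return 0.0
    return math.sqrt(max(1.0 - lam2 / lam1, 0.0))


# --------------------------------------------------------------------------
# Vessel field


def add_rect_vessel(grid: np.ndarray, start: tuple[float, float],
                    angle_deg: float, length_px: float,
                    width_px: float) -> tuple[int, float]:
    """Stamp a flat-capped thick segment; returns (new pixels, length).

    The stroke covers pixel centres whose projection onto the direction lies
    in [0, length) and whose perpendicular distance is <= width/2, so an
    axis-aligned stroke is an exact length x width pixel rectangle.
    """
    r0, c0 = start
    ang = math.radians(angle_deg)
    ur, uc = math.sin(ang), math.cos(ang)  # row grows downward
    half = width_px / 2.0
    # local bounding box
    r1, c1 = r0 + ur * (length_px - 1), c0 + uc * (length_px - 1)
    lo_r = max(int(math.floor(min(r0, r1) - half - 1)), 0)
    hi_r = min(int(math.ceil(max(r0, r1) + half + 1)), grid.shape[0] - 1)
    lo_c = max(int(math.floor(min(c0, c1) - half - 1)), 0)
    hi_c = min(int(math.ceil(max(c0, c1) + half + 1)), grid.shape[1] - 1)
    if hi_r < lo_r or hi_c < lo_c:
        return 0, 0.0
    rr, cc = np.mgrid[lo_r:hi_r + 1, lo_c:hi_c + 1]
    dr = rr - r0
    dc = cc - c0
    t = dr * ur + dc * uc
    d = np.abs(dr * uc - dc * ur)
    stamp = (t >= -1e-9) & (t < length_px - 1e-9) & (d <= half + 1e-9)
    sub = grid[lo_r:hi_r + 1, lo_c:hi_c + 1]
    new = int(np.count_nonzero(stamp & ~sub))
    sub |= stamp
    return new, float(length_px)


def make_vessel_field(spec: PhantomSpec,
                      rng: np.random.Generator | None = None,
                      cap_gaps: bool = False,
                      ) -> tuple[np.ndarray, PhantomTruth]:
    """Random curvilinear vessel strokes at the target areal fraction.

    Strokes are random-walk centrelines (step 4 px, Gaussian heading
    drift) stamped as flat-capped thick segments.  Each stroke starts at
    the least-covered of eight candidate positions (dart throwing), which
    spreads the mesh homogeneously the way a perifoveal capillary plexus
    is: inter-capillary gaps stay capillary-scale instead of leaving large
    random voids that could rival the FAZ.  Drawing stops as soon as the
    covered fraction reaches the target, which bounds the overshoot by a
    fraction of one stroke (well inside 2 percentage points at defaults).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    grid = np.zeros((n, n), dtype=bool)
    target = spec.vessel_fraction * n * n
    covered = 0
    total_len_px = 0.0
    step = 4.0
    max_strokes = 20000
    for _ in range(max_strokes):
        if covered >= target:
            break
        starts = rng.uniform(0, n, size=(8, 2))
        covs = [grid[max(0, int(r) - 10):int(r) + 11,
                     max(0, int(c) - 10):int(c) + 11].mean()
                for r, c in starts]
        r, c = starts[int(np.argmin(covs))]
        heading = rng.uniform(0.0, 360.0)
        width = max(1.0, rng.normal(spec.vessel_width_px,
                                    0.15 * spec.vessel_width_px))
        n_steps = int(rng.integers(20, 80))
        for _ in range(n_steps):
            heading += rng.normal(0.0, 18.0)
            new, seg_len = add_rect_vessel(grid, (r, c), heading, step, width)
            covered += new
            # count only the in-frame part of the centreline
            r2 = r + math.sin(math.radians(heading)) * step
            c2 = c + math.cos(math.radians(heading)) * step
            if 0 <= r < n and 0 <= c < n:
                total_len_px += seg_len
            r, c = r2, c2
            if not (-10 < r < n + 10 and -10 < c < n + 10):
                break
            if covered >= target:
                break
    if cap_gaps and spec.max_gap_px > 0 and spec.vessel_fraction > 0:
        total_len_px += _fill_oversized_gaps(grid, spec, rng)
    truth = PhantomTruth(
        faz_mask=np.zeros((n, n), dtype=bool),
        true_area=0.0,
        true_eccentricity=0.0,
        true_vessel_length=total_len_px * spec.scale,
        true_vessel_area=float(grid.sum()) * spec.scale ** 2,
        scale=spec.scale,
    )
    return grid, truth


# --------------------------------------------------------------------------
# Full phantom


def _fill_oversized_gaps(grid: np.ndarray, spec: PhantomSpec,
                         rng: np.random.Generator) -> float:
    """Run extra strokes through any background gap above max_gap_px.

    Returns the added centreline length in px.  Converges because every
    pass subdivides the offending gaps; a generous iteration cap guards
    degenerate settings (very low target fractions keep their large gaps).
    """
    from scipy import ndimage as ndi

    step = 4.0
    added = 0.0
    eight = np.ones((3, 3), dtype=int)
    for _ in range(50):
        labels, n = ndi.label(~grid, structure=eight)
        if n == 0:
            break
        sizes = ndi.sum_labels(~grid, labels, index=np.arange(1, n + 1))
        big = np.nonzero(sizes > spec.max_gap_px)[0] + 1
        if big.size == 0:
            break
        cents = ndi.center_of_mass(~grid, labels, index=big)
        for (r, c) in cents:
            heading = rng.uniform(0.0, 360.0)
            width = max(1.0, rng.normal(spec.vessel_width_px,
                                        0.15 * spec.vessel_width_px))
            for _ in range(12):
                heading += rng.normal(0.0, 18.0)
                add_rect_vessel(grid, (r, c), heading, step, width)
                if 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]:
                    added += step
                r += math.sin(math.radians(heading)) * step
                c += math.cos(math.radians(heading)) * step
    return added


def make_faz_phantom(spec: PhantomSpec) -> tuple[EnFaceImage, PhantomTruth]:
    """Render a phantom angiogram and its exact ground truth.

    The frame is a mid-grey background with bright vessel strokes, the FAZ
    overwritten dark (vessels never cross it), and Gaussian noise added.
    Identical specs (including seed) give bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    faz_mask, ecc = _rasterize_faz(spec)
    vessels, vtruth = make_vessel_field(spec, rng=rng, cap_gaps=True)
    vessels_visible = vessels & ~faz_mask

    img = np.full(faz_mask.shape, BACKGROUND_LEVEL, dtype=float)
    img[vessels_visible] = VESSEL_LEVEL
    img[faz_mask] = FAZ_LEVEL
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = PhantomTruth(
        faz_mask=faz_mask,
        true_area=float(faz_mask.sum()) * spec.scale ** 2,
        true_eccentricity=ecc,
        true_vessel_length=vtruth.true_vessel_length,
        true_vessel_area=float(vessels_visible.sum()) * spec.scale ** 2,
        scale=spec.scale,
    )
    image = EnFaceImage(pixels=img, scale=spec.scale, plexus="SCP",
                        eye_id=f"phantom-{spec.seed}")
    return image, truth


# --------------------------------------------------------------------------
# Synthetic cohorts

# Planted group conditions: per-variable (responder mean, non-responder
# mean, responder SD, non-responder SD), emulating the reported responder /
# non-responder contrasts in a 61-eye anti-VEGF DME cohort.
DEFAULT_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "vd_outer_scp": (15.5, 14.55, 2.2, 3.57),
    "vd_full_scp": (15.29, 14.24, 2.4, 3.51),
    "pd_outer_scp": (38.79, 36.17, 5.9, 9.6),
    "pd_full_scp": (37.93, 35.41, 6.22, 9.32),
    "vdi_dcp": (27.01, 33.56, 7.88, 16.95),
    "faz_area_scp": (0.30, 0.30, 0.20, 0.24),
    "faz_circularity_scp": (0.77, 0.79, 0.24, 0.19),
}

# Fractional CST reduction (x - y)/x by planted group: responders show a
# large reduction, non-responders little or none.
DEFAULT_CST_CHANGE = {"responder": (0.40, 0.12), "nonresponder": (0.05, 0.10)}


def make_cohort(n_eyes: int = 61,
                effects: dict[str, tuple[float, float, float, float]]
                | None = None,
                seed: int = 0,
                cst_change: dict[str, tuple[float, float]] | None = None,
                ) -> pd.DataFrame:
    """Simulate a per-eye cohort table with planted group effects.

    The first ``n_eyes // 2`` records are planted responders (the quartile
    rule assigns floor(n/2) eyes to the responder group), the rest
    non-responders.  Baseline CST, demographics and every variable in
    ``effects`` are drawn per group; post-treatment CST is derived from the
    planted fractional change.  Setting equal group means (and equal
    ``cst_change`` parameters) yields a null cohort.
    """
    if n_eyes < 4:
        raise ValueError("n_eyes must be >= 4")
    if effects is None:
        effects = DEFAULT_EFFECTS
    if cst_change is None:
        cst_change = DEFAULT_CST_CHANGE
    for name, (_, _, sd_r, sd_n) in effects.items():
        if sd_r <= 0 or sd_n <= 0:
            raise ValueError(f"non-positive SD for {name!r}")
    for grp, (_, sd) in cst_change.items():
        if sd <= 0:
            raise ValueError(f"non-positive CST-change SD for {grp!r}")

    rng = np.random.default_rng(seed)
    n_resp = n_eyes // 2
    groups = np.array(["responder"] * n_resp +
                      ["nonresponder"] * (n_eyes - n_resp))
    is_resp = groups == "responder"

    age = np.where(is_resp, rng.normal(57.5, 6.5, n_eyes),
                   rng.normal(60.1, 8.4, n_eyes))
    sex = rng.choice(["M", "F"], size=n_eyes, p=[0.69, 0.31])
    duration = np.clip(np.where(is_resp, rng.normal(13.8, 7.5, n_eyes),
                                rng.normal(14.8, 9.5, n_eyes)), 0.5, None)
    cst_base = np.clip(np.where(is_resp, rng.normal(494.0, 161.5, n_eyes),
                                rng.normal(421.7, 121.7, n_eyes)), 220, None)
    mu_r, sd_r = cst_change["responder"]
    mu_n, sd_n = cst_change["nonresponder"]
    change = np.where(is_resp, rng.normal(mu_r, sd_r, n_eyes),
                      rng.normal(mu_n, sd_n, n_eyes))
    cst_post = cst_base * (1.0 - change)
    bcva = np.clip(np.where(is_resp, rng.normal(0.5, 0.3, n_eyes),
                            rng.normal(0.6, 0.3, n_eyes)), 0.0, 2.0)
    signal = rng.integers(7, 11, size=n_eyes)

    data = {
        "eye_id": [f"E{i + 1:03d}" for i in range(n_eyes)],
        "group_true": groups,
        "age": np.round(age, 1),
        "sex": sex,
        "diabetes_duration": np.round(duration, 1),
        "signal_strength": signal,
        "cst_baseline": np.round(cst_base, 1),
        "cst_post": np.round(cst_post, 1),
        "bcva_logmar": np.round(bcva, 2),
    }
    for name, (m_r, m_n, s_r, s_n) in effects.items():
        vals = np.where(is_resp, rng.normal(m_r, s_r, n_eyes),
                        rng.normal(m_n, s_n, n_eyes))
        data[name] = vals
    return pd.DataFrame(data)


def null_cohort(n_eyes: int = 61, seed: int = 0) -> pd.DataFrame:
    """Cohort with no planted group differences anywhere."""
    effects = {k: (v[0], v[0], v[2], v[2]) for k, v in
               DEFAULT_EFFECTS.items()}
    change = {"responder": (0.15, 0.15), "nonresponder": (0.15, 0.15)}
    return make_cohort(n_eyes, effects=effects, seed=seed, cst_change=change)
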
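"""Readers, writers, pipeline configuration and the end-to-end run.

Images come in as 8-bit single-channel PNG/TIFF (RGB is converted by
luminance and higher bit depths are rescaled, both with a warning);
cohorts are CSV with a documented header schema.  Every output directory
receives a JSON run manifest carrying the config hash, seed and library
versions so reruns with unchanged config + seed are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (compare_groups, contribution_frame, contribution_table,
                     comparisons_frame, filter_by_signal,
                     percentage_change_cst, quartile_split)
from .etdrs import build_etdrs_grid, compute_ring_densities
from .segmentation import SegmentationConfig, segment_faz
from .shape import compute_shape_params
from .synthetic import PhantomSpec, make_cohort, make_faz_phantom
from .types import EnFaceImage, SegmentationError
from .vessels import binarize_vessels, compute_vessel_stats, \
    skeletonize_vessels

log = logging.getLogger("octafaz")

REQUIRED_COHORT_COLUMNS = ("eye_id", "cst_baseline", "cst_post",
                           "signal_strength")


class SchemaError(ValueError):
    """Raised when a cohort CSV violates the documented schema."""


def read_image(path, field_mm: float = 6.0, scale: float | None = None,
               plexus: str = "SCP", eye_id: str | None = None) -> EnFaceImage:
    """Load an en-face angiogram from PNG/TIFF.

    ``scale`` defaults to field width / pixel width (a 6-mm field unless
    stated otherwise); ``eye_id`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    px = iio.imread(path)
    if px.ndim == 3:
        warnings.warn(f"{path.name}: RGB input converted by luminance")
        px = (0.2126 * px[..., 0] + 0.7152 * px[..., 1]
              + 0.0722 * px[..., 2])
    if px.dtype != np.uint8:
        peak = px.max()
        if peak > 255:
            warnings.warn(f"{path.name}: >8-bit input rescaled to 8 bit")
            px = px.astype(float) * (255.0 / peak)
    px = np.clip(np.rint(np.asarray(px, dtype=float)), 0, 255).astype(np.uint8)
    if scale is None:
        scale = field_mm / px.shape[1]
    return EnFaceImage(pixels=px, scale=scale, plexus=plexus,
                       eye_id=eye_id or path.stem)


def write_image(path, pixels: np.ndarray) -> None:
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_cohort(path) -> pd.DataFrame:
    """Load and validate a cohort CSV.

    Requires columns eye_id, cst_baseline, cst_post, signal_strength;
    malformed rows (non-positive CST, out-of-range signal strength) are
    reported with their 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    bad = []
    for i, row in df.iterrows():
        if row["cst_baseline"] <= 0 or row["cst_post"] <= 0:
            bad.append((i + 1, "non-positive CST"))
        if not 0 <= row["signal_strength"] <= 10:
            bad.append((i + 1, "signal_strength outside [0, 10]"))
    if bad:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad)
        raise SchemaError(f"invalid cohort rows: {detail}")
    return df


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], outdir,
                  config: dict | None = None, seed: int | None = None) -> dict:
    """Write result CSVs plus a JSON run manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        files[name] = p.name
    manifest = {
        "octafaz_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# Pipeline configuration and end-to-end run


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    n_eyes: int = 12
    seed: int = 0
    image_size: int = 420
    field_mm: float = 6.0
    faz_radius_mm: float = 0.35
    noise_sd: float = 8.0
    vessel_fraction: float = 0.45
    binarization: str = "otsu"
    laterality: str = "OD"
    alpha: float = 0.05
    min_signal_strength: int = 7
    welch: bool = False
    segmentation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def scale(self) -> float:
        return self.field_mm / self.image_size

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.segmentation)


COMPARE_VARIABLES = ["vd_outer_scp", "vd_full_scp", "pd_outer_scp",
                     "pd_full_scp", "vdi_dcp", "faz_area_scp",
                     "faz_circularity_scp"]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate, segment, measure and compare one synthetic cohort.

    Per-eye failures (e.g. segmentation failure on a degenerate image) are
    logged and skipped, never fatal; the returned summary lists them.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = make_cohort(n_eyes=config.n_eyes, seed=config.seed)
    cohort = filter_by_signal(cohort, config.min_signal_strength)

    per_eye_rows = []
    skipped = []
    seg_cfg = config.segmentation_config()
    for i, eye_id in enumerate(cohort["eye_id"]):
        spec = PhantomSpec(
            faz_shape="blob",
            radius_mm=config.faz_radius_mm * float(rng.uniform(0.7, 1.3)),
            acircularity=float(rng.uniform(0.0, 0.25)),
            vessel_fraction=config.vessel_fraction,
            noise_sd=config.noise_sd,
            image_size=config.image_size,
            scale=config.scale,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            image, truth = make_faz_phantom(spec)
            mask = segment_faz(image, seg_cfg)
            params = compute_shape_params(mask.infill, image.scale)
            vstats = compute_vessel_stats(image)
            vmask = binarize_vessels(image, method=config.binarization)
            skel = skeletonize_vessels(vmask)
            grid = build_etdrs_grid(image.pixels.shape, image.scale,
                                    laterality=config.laterality)
            dens = compute_ring_densities(vmask, skel, grid)
            row = {"eye_id": eye_id, **params.as_dict(),
                   "tortuosity": vstats.tortuosity,
                   "vdi_px": vstats.vessel_diameter_index_px,
                   "vessel_avascular_density":
                       vstats.vessel_avascular_density,
                   **dens.__dict__,
                   "true_faz_area": truth.true_area}
            per_eye_rows.append(row)
            log.info("eye=%s stage=measured area=%.3f", eye_id, params.area)
        except (SegmentationError, ValueError) as exc:
            skipped.append((eye_id, str(exc)))
            log.warning("eye=%s stage=skipped reason=%s", eye_id, exc)

    change = percentage_change_cst(cohort["cst_baseline"],
                                   cohort["cst_post"])
    cohort = cohort.assign(cst_change=change,
                           group=quartile_split(change))
    comparisons = compare_groups(cohort, COMPARE_VARIABLES,
                                 alpha=config.alpha, welch=config.welch)
    significant = [c for c in comparisons if c.significant] or comparisons
    contrib = contribution_table(
        {c.variable: round(c.mean_r, 2) for c in significant},
        {c.variable: round(c.mean_n, 2) for c in significant})

    tables = {
        "per_eye_metrics": pd.DataFrame(per_eye_rows),
        "cohort": cohort,
        "comparisons": comparisons_frame(comparisons),
        "contribution": contribution_frame(contrib),
    }
    manifest = write_results(tables, outdir, config=config.to_dict(),
                             seed=config.seed)
    manifest["skipped_eyes"] = skipped
    manifest["n_processed"] = len(per_eye_rows)
    return manifest
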
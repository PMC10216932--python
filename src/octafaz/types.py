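"""Core data containers shared across the pipeline.

An en-face OCTA image is a 2-D grid of 8-bit decorrelation intensities for
one retinal plexus (superficial or deep capillary plexus) of one eye,
together with the physical sampling scale in millimetres per pixel.  A FAZ
mask is the segmented foveal avascular zone: a single filled connected
region plus its ordered boundary contour, in full-field coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PLEXUSES = ("SCP", "DCP")


class SegmentationError(RuntimeError):
    """Raised when no plausible FAZ region survives the pipeline."""


@dataclass(frozen=True)
class EnFaceImage:
    """8-bit grayscale en-face angiogram with physical scale.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Decorrelation intensities; flow is bright, avascular tissue dark.
    scale : float
        Millimetres per pixel (isotropic).  A 6 mm field sampled at
        420 px gives scale = 6/420 ≈ 0.0143 mm/px.
    plexus : {"SCP", "DCP"}
    eye_id : str
    """

    pixels: np.ndarray
    scale: float
    plexus: str = "SCP"
    eye_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.plexus not in PLEXUSES:
            raise ValueError(f"plexus must be one of {PLEXUSES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_mm(self) -> tuple[float, float]:
        """Physical extent (height, width) in mm."""
        return (self.pixels.shape[0] * self.scale,
                self.pixels.shape[1] * self.scale)


@dataclass
class FazMask:
    """Segmented FAZ: filled binary region and its traced outline.

    ``infill`` is a boolean grid in full-field coordinates with exactly one
    8-connected foreground component and no interior holes.  ``outline`` is
    the ordered (row, col) boundary pixel list produced by Moore-neighbour
    tracing of that component.
    """

    infill: np.ndarray
    outline: np.ndarray
    scale: float
    eye_id: str = ""
    plexus: str = "SCP"
    stage_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.infill = np.asarray(self.infill, dtype=bool)
        self.outline = np.asarray(self.outline, dtype=int).reshape(-1, 2)
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def area_px(self) -> int:
        return int(self.infill.sum())
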
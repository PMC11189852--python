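"""Digital kidney phantom: an elliptical parenchyma with a cortical rim.

The phantom is deliberately stylized: an outer ellipse of cortex
surrounding an inner elliptical medulla, on a 2-D slice (stack slices for
3-D).  The default geometry keeps the cortex/medulla area ratio near the
~2.8:1 ratio seen in manually drawn kidney ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RenalDwiError

__all__ = ["PhantomGeometry", "PhantomLabelMap", "build_phantom", "jitter_labels",
           "BACKGROUND", "CORTEX", "MEDULLA", "REGION_LABELS"]

BACKGROUND, CORTEX, MEDULLA = 0, 1, 2
REGION_LABELS = {"cortex": CORTEX, "medulla": MEDULLA}


@dataclass(frozen=True)
class PhantomGeometry:
    nx: int = 48
    ny: int = 48
    outer_semiaxes: tuple[float, float] = (20.0, 13.0)   # voxels
    medulla_scale: float = 0.514    # inner/outer semiaxis ratio
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)


@dataclass
class PhantomLabelMap:
    """Integer label volume: 0 background, 1 cortex, 2 medulla."""

    labels: np.ndarray                      # (nx, ny, nz) int
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 2:
            self.labels = self.labels[:, :, None]
        if self.labels.ndim != 3:
            raise RenalDwiError("label map must be 2-D or 3-D")
        cortex = int((self.labels == CORTEX).sum())
        medulla = int((self.labels == MEDULLA).sum())
        if cortex == 0 or medulla == 0:
            raise RenalDwiError("cortex and medulla must both be non-empty")

    def mask(self, region: str) -> np.ndarray:
        if region not in REGION_LABELS:
            raise RenalDwiError(f"unknown region {region!r}")
        return self.labels == REGION_LABELS[region]

    def count(self, region: str) -> int:
        return int(self.mask(region).sum())

    @property
    def kidney_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND


def build_phantom(geometry: PhantomGeometry | None = None) -> PhantomLabelMap:
    """Deterministically rasterize the two-region kidney phantom."""
    geo = geometry or PhantomGeometry()
    if geo.nx < 32 or geo.ny < 32:
        raise RenalDwiError("phantom grid must be at least 32x32")
    ax, ay = geo.outer_semiaxes
    if ax <= 0 or ay <= 0:
        raise RenalDwiError("outer semiaxes must be positive")
    if not 0.0 < geo.medulla_scale < 1.0:
        raise RenalDwiError("medulla_scale must lie strictly in (0, 1)")
    rim = (1.0 - geo.medulla_scale) * min(ax, ay)
    if rim < 1.0:
        raise RenalDwiError(
            f"cortical rim thickness {rim:.2f} voxels is below the 1-voxel minimum"
        )
    cx, cy = (geo.nx - 1) / 2.0, (geo.ny - 1) / 2.0
    x = np.arange(geo.nx)[:, None] - cx
    y = np.arange(geo.ny)[None, :] - cy
    r_outer = (x / ax) ** 2 + (y / ay) ** 2
    s = geo.medulla_scale
    r_inner = (x / (s * ax)) ** 2 + (y / (s * ay)) ** 2
    labels = np.zeros((geo.nx, geo.ny), int)
    labels[r_outer <= 1.0] = CORTEX
    labels[r_inner <= 1.0] = MEDULLA
    return PhantomLabelMap(labels=labels, voxel_size_mm=geo.voxel_size_mm)


def jitter_labels(
    label_map: PhantomLabelMap, flip_fraction: float = 0.1, seed: int | None = None
) -> PhantomLabelMap:
    """Emulate a second observer's ROI by eroding a random subset of
    region-boundary voxels to background.

    Used to exercise the inter-observer agreement (ICC) analysis; the
    phantom has no real observers.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise RenalDwiError("flip_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = label_map.labels.copy()
    lab2d = labels[:, :, 0]
    boundary = np.zeros_like(lab2d, bool)
    for shift_ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(lab2d, shift, axis=shift_ax)
        boundary |= (lab2d != BACKGROUND) & (rolled != lab2d)
    idx = np.flatnonzero(boundary)
    drop = rng.choice(idx, size=int(round(flip_fraction * idx.size)), replace=False)
    lab2d.flat[drop] = BACKGROUND
    return PhantomLabelMap(labels=labels, voxel_size_mm=label_map.voxel_size_mm)
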
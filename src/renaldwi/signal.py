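"""Forward signal models and magnitude (Rician) noise.

Unit convention used throughout the package: diffusivities in um^2/ms,
b values in s/mm^2, echo/relaxation times in ms.  The product
b [s/mm^2] * D [um^2/ms] is made dimensionless with a factor 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError, RenalDwiError
from .protocol import B_SCALE, AcquisitionProtocol

__all__ = [
    "TissueGroundTruth",
    "ImageSeries",
    "forward_ivim_kurtosis",
    "forward_dt2",
    "forward_signal",
    "add_rician_noise",
    "rician_mean_magnitude",
    "rician_debias",
    "estimate_noise_sigma",
]

FORWARD_MODELS = ("ivim_kurtosis", "dt2")


@dataclass(frozen=True)
class TissueGroundTruth:
    """Generating parameters for one tissue (one phantom region).

    ``f_perf``         perfusion (pseudo-diffusion) fraction, 0..1
    ``d_tissue``       tissue diffusivity, um^2/ms
    ``d_star``         pseudo-diffusion coefficient, um^2/ms (> d_tissue)
    ``mk``             mean kurtosis, dimensionless (>= 0)
    ``spectrum_components``  list of (d, t2, weight) for the D-T2 model;
                             weights sum to 1
    ``s0``             fully relaxed, unweighted signal, arbitrary units
    """

    f_perf: float
    d_tissue: float
    d_star: float
    mk: float
    spectrum_components: tuple[tuple[float, float, float], ...] = ()
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_perf <= 1.0:
            raise RenalDwiError("f_perf must lie in [0, 1]")
        for name, val in (("d_tissue", self.d_tissue), ("d_star", self.d_star)):
            if not 0.0 < val <= 300.0:
                raise RenalDwiError(f"{name} must lie in (0, 300] um^2/ms")
        if self.d_star <= self.d_tissue:
            raise RenalDwiError("d_star must exceed d_tissue")
        if self.mk < 0:
            raise RenalDwiError("mk must be non-negative")
        comps = tuple(tuple(map(float, c)) for c in self.spectrum_components)
        if comps:
            w = np.array([c[2] for c in comps])
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise RenalDwiError("spectrum component weights must be >= 0 and sum to 1")
            if any(not (0 < c[0] <= 30) for c in comps):
                raise RenalDwiError("component diffusivities must lie in (0, 30] um^2/ms")
            if any(c[1] <= 0 for c in comps):
                raise RenalDwiError("component T2 values must be positive")
        object.__setattr__(self, "spectrum_components", comps)


@dataclass
class ImageSeries:
    """A 4-D volume stack: one 3-D volume per acquisition point."""

    data: np.ndarray                 # (nx, ny, nz, n_points)
    protocol: AcquisitionProtocol
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise RenalDwiError("ImageSeries data must be 4-D (x, y, z, point)")
        if self.data.shape[-1] != len(self.protocol):
            raise RenalDwiError(
                f"series has {self.data.shape[-1]} volumes but protocol "
                f"{self.protocol.name!r} defines {len(self.protocol)} points"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def forward_ivim_kurtosis(
    b: np.ndarray,
    s0: float,
    f_perf: float,
    d_tissue: float,
    d_star: float,
    mk: float,
) -> np.ndarray:
    """Bi-exponential IVIM with a kurtosis correction on the tissue pool.

    S(b) = S0 [ f e^{-b D* 1e-3} + (1-f) e^{-b D 1e-3 + (1/6) MK (b D 1e-3)^2} ]

    The perfusion fraction multiplies the fast (pseudo-diffusion) term.
    """
    b = np.asarray(b, float)
    bd = b * d_tissue * B_SCALE
    tissue = np.exp(-bd + mk * bd**2 / 6.0)
    perf = np.exp(-b * d_star * B_SCALE)
    return s0 * (f_perf * perf + (1.0 - f_perf) * tissue)


def forward_dt2(
    b: np.ndarray,
    te: np.ndarray,
    s0: float,
    components: tuple[tuple[float, float, float], ...],
) -> np.ndarray:
    """Discrete D-T2 forward model: sum of w * e^{-b d 1e-3} * e^{-TE/t2}."""
    b = np.asarray(b, float)
    te = np.asarray(te, float)
    out = np.zeros_like(b, dtype=float)
    for d, t2, w in components:
        out += w * np.exp(-b * d * B_SCALE) * np.exp(-te / t2)
    return s0 * out


def forward_signal(
    gt: TissueGroundTruth, protocol: AcquisitionProtocol, model: str
) -> np.ndarray:
    """Noiseless signal for one tissue under one protocol.

    ``model`` is ``ivim_kurtosis`` (uses f_perf, d_tissue, d_star, mk) or
    ``dt2`` (uses spectrum_components; requires a protocol with at least
    two distinct echo times).
    """
    if model == "ivim_kurtosis":
        return forward_ivim_kurtosis(
            protocol.b, gt.s0, gt.f_perf, gt.d_tissue, gt.d_star, gt.mk
        )
    if model == "dt2":
        if protocol.n_distinct_te < 2:
            raise ProtocolError(
                "dt2 forward model needs a protocol with >= 2 distinct TEs"
            )
        if not gt.spectrum_components:
            raise RenalDwiError("dt2 model needs spectrum_components on the ground truth")
        return forward_dt2(protocol.b, protocol.te, gt.s0, gt.spectrum_components)
    raise RenalDwiError(f"unknown forward model {model!r}; one of {FORWARD_MODELS}")


def add_rician_noise(
    series: np.ndarray,
    sigma: float,
    n_avg: np.ndarray | int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Replace each point by the mean of ``n_avg`` magnitude (Rician) draws.

    Each draw is sqrt((S + g1)^2 + g2^2) with g1, g2 ~ Normal(0, sigma):
    magnitude reconstruction of a complex signal with independent channel
    noise.  Averaging magnitude draws (not scaling sigma) matches how
    scanners average repeated acquisitions.

    ``series`` may be (n_points,) or (n_voxels, n_points); ``n_avg`` is a
    scalar or a per-point integer array.
    """
    if sigma < 0:
        raise RenalDwiError("sigma must be non-negative")
    series = np.asarray(series, float)
    if sigma == 0:
        return series.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = series.reshape(-1, series.shape[-1])
    n_points = flat.shape[1]
    n_avg_arr = np.broadcast_to(np.asarray(n_avg, int), (n_points,))
    out = np.empty_like(flat)
    for i in range(n_points):
        n = int(n_avg_arr[i])
        g1 = rng.normal(0.0, sigma, size=(n, flat.shape[0]))
        g2 = rng.normal(0.0, sigma, size=(n, flat.shape[0]))
        out[:, i] = np.sqrt((flat[:, i][None, :] + g1) ** 2 + g2**2).mean(axis=0)
    return out.reshape(series.shape)


def rician_mean_magnitude(s: np.ndarray, sigma: float) -> np.ndarray:
    """Expected magnitude of a Rician variable with amplitude ``s``.

    E[M] = sigma sqrt(pi/2) L_{1/2}(-s^2 / 2 sigma^2), evaluated with
    exponentially scaled Bessel functions for numerical stability.
    Averaging n independent magnitudes leaves the expectation unchanged.
    """
    from scipy.special import ive

    s = np.asarray(s, float)
    x = -(s**2) / (2.0 * sigma**2)
    z = -x / 2.0
    laguerre = np.exp(x / 2.0 + z) * ((1.0 - x) * ive(0, z) - x * ive(1, z))
    return sigma * np.sqrt(np.pi / 2.0) * laguerre


def rician_debias(magnitudes: np.ndarray, sigma: float) -> np.ndarray:
    """Invert the Rician mean-magnitude map: estimate the underlying
    amplitude from an observed (possibly averaged) magnitude.

    Observations at or below the zero-amplitude noise floor
    sigma sqrt(pi/2) map to 0.  Exact for ensemble/ROI means; for single
    noisy magnitudes it removes the bias in expectation only.
    """
    from scipy.optimize import brentq

    if sigma < 0:
        raise RenalDwiError("sigma must be non-negative")
    mags = np.asarray(magnitudes, float)
    if sigma == 0:
        return mags.copy()
    floor = sigma * np.sqrt(np.pi / 2.0)
    out = np.zeros_like(mags)
    flat_in = mags.ravel()
    flat_out = out.ravel()
    for i, m in enumerate(flat_in):
        if m > floor * (1.0 + 1e-12):
            flat_out[i] = brentq(
                lambda s: rician_mean_magnitude(s, sigma) - m, 0.0, m + 5.0 * sigma
            )
    return flat_out.reshape(mags.shape)


def estimate_noise_sigma(image: "ImageSeries", background_mask: np.ndarray) -> float:
    """Channel-noise sigma from pure-noise (background) voxels.

    The mean magnitude of a zero-signal Rician is sigma sqrt(pi/2),
    independent of the number of averages, so the estimate pools all
    background voxels and acquisition points.
    """
    background_mask = np.asarray(background_mask, bool)
    values = image.data[background_mask, :]
    if values.size == 0:
        raise RenalDwiError("background mask selects no voxels")
    return float(values.mean() / np.sqrt(np.pi / 2.0))
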
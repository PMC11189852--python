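"""D-T2 spectrum inversion (DR-CSI) and compartment analysis.

The multi-TE-multi-b signal is modelled as a non-negative mixture over a
fixed 30 x 30 mesh of (diffusivity, T2) "components":

    S_i = sum_{j,k} f(D_j, T2_k) exp(-b_i D_j 1e-3) exp(-TE_i / T2_k)

Inversion is a Tikhonov-regularized non-negative least squares solve.
The recovered spectrum is partitioned into three compartments:

    A  low diffusivity, short T2   (intracellular-like)
    B  low diffusivity, long T2    (extracellular-like)
    C  high diffusivity            (flow-like)

with boundaries placed automatically at the emptiest gridline inside the
physiologically stated search windows (T2 within 30-50 ms, D within
6-9 um^2/ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import GridMismatchError, ProtocolError, RenalDwiError
from .protocol import B_SCALE, AcquisitionProtocol

__all__ = [
    "DT2Mesh",
    "DT2Spectrum",
    "CompartmentPartition",
    "FractionTriple",
    "build_kernel",
    "default_lambda",
    "invert_spectrum",
    "choose_boundaries",
    "compartment_fractions",
]

COMPARTMENTS = ("A", "B", "C")


@dataclass(frozen=True)
class DT2Mesh:
    """Log-spaced (D, T2) mesh; both endpoints included (geometric grid)."""

    n_d: int = 30
    n_t2: int = 30
    d_range: tuple[float, float] = (0.3, 30.0)     # um^2/ms
    t2_range: tuple[float, float] = (5.0, 200.0)   # ms
    d: np.ndarray = field(init=False, repr=False)
    t2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.geomspace(*self.d_range, self.n_d))
        object.__setattr__(self, "t2", np.geomspace(*self.t2_range, self.n_t2))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_d, self.n_t2)

    @property
    def size(self) -> int:
        return self.n_d * self.n_t2

    def nearest(self, d: float, t2: float) -> tuple[int, int]:
        """Indices of the mesh point closest to (d, t2) in log coordinates."""
        j = int(np.argmin(np.abs(np.log(self.d) - np.log(d))))
        k = int(np.argmin(np.abs(np.log(self.t2) - np.log(t2))))
        return j, k

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DT2Mesh)
            and self.shape == other.shape
            and self.d_range == other.d_range
            and self.t2_range == other.t2_range
        )


@dataclass
class DT2Spectrum:
    """Non-negative intensity over a DT2Mesh (D along axis 0, T2 along 1)."""

    intensity: np.ndarray
    mesh: DT2Mesh
    source: str = "voxel"     # "voxel" or "roi"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        if self.intensity.shape != self.mesh.shape:
            raise GridMismatchError(
                f"spectrum shape {self.intensity.shape} != mesh shape {self.mesh.shape}"
            )
        if np.any(self.intensity < -1e-12):
            raise RenalDwiError("spectral intensity must be non-negative")
        self.intensity = np.clip(self.intensity, 0.0, None)

    @property
    def total_mass(self) -> float:
        return float(self.intensity.sum())

    def normalized(self) -> "DT2Spectrum":
        """Unit-total-mass copy (the normalization used before CMD subtraction)."""
        mass = self.total_mass
        if mass <= 0:
            raise RenalDwiError("cannot normalize a zero-mass spectrum")
        return DT2Spectrum(self.intensity / mass, self.mesh, self.source)


@dataclass(frozen=True)
class CompartmentPartition:
    """Compartment masks induced by a (d_boundary, t2_boundary) pair.

    C = {D > d_boundary}; A = {D <= d_boundary, T2 <= t2_boundary};
    B = {D <= d_boundary, T2 > t2_boundary}.
    """

    mesh: DT2Mesh
    d_boundary: float      # um^2/ms
    t2_boundary: float     # ms

    def masks(self) -> dict[str, np.ndarray]:
        shape = self.mesh.shape
        d_low = np.broadcast_to(self.mesh.d[:, None] <= self.d_boundary, shape)
        t2_short = np.broadcast_to(self.mesh.t2[None, :] <= self.t2_boundary, shape)
        return {"A": d_low & t2_short, "B": d_low & ~t2_short, "C": ~d_low}

    def to_json_dict(self) -> dict:
        return {
            "d_boundary_um2_ms": self.d_boundary,
            "t2_boundary_ms": self.t2_boundary,
            "rule": "C: D > d_boundary; A: D <= d_boundary and T2 <= t2_boundary; "
                    "B: D <= d_boundary and T2 > t2_boundary",
        }


@dataclass(frozen=True)
class FractionTriple:
    """Compartment volume fractions; they sum to 1 by construction."""

    v_a: float
    v_b: float
    v_c: float

    def __post_init__(self) -> None:
        for v in (self.v_a, self.v_b, self.v_c):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise RenalDwiError("fractions must lie in [0, 1]")
        if abs(self.v_a + self.v_b + self.v_c - 1.0) > 1e-9:
            raise RenalDwiError("fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"A": self.v_a, "B": self.v_b, "C": self.v_c}


def build_kernel(protocol: AcquisitionProtocol, mesh: DT2Mesh | None = None) -> np.ndarray:
    """Forward operator: (n_points, n_d * n_t2), row i, column j*n_t2 + k is
    exp(-b_i D_j 1e-3) exp(-TE_i / T2_k)."""
    mesh = mesh or DT2Mesh()
    if protocol.n_distinct_te < 2:
        raise ProtocolError(
            "D-T2 inversion needs >= 2 distinct echo times (single-TE protocols "
            "are unidentifiable in T2)"
        )
    decay_d = np.exp(-np.outer(protocol.b, mesh.d) * B_SCALE)       # (n, n_d)
    decay_t2 = np.exp(-np.outer(protocol.te, 1.0 / mesh.t2))        # (n, n_t2)
    kernel = decay_d[:, :, None] * decay_t2[:, None, :]
    return kernel.reshape(len(protocol), mesh.size)


def default_lambda(kernel: np.ndarray, scale: float = 0.001) -> float:
    """Default Tikhonov weight: ``scale`` times the largest singular value.

    The 1e-3 scale balances noise suppression against compartment-fraction
    distortion: short-T2 components decay fast, so an overly strong
    penalty on ||f|| suppresses their (necessarily larger) coefficients
    and silently shifts mass toward long-T2 mesh points.
    """
    return scale * float(np.linalg.norm(kernel, 2))


def invert_spectrum(
    series: np.ndarray,
    kernel: np.ndarray,
    lambda_reg: float | None = None,
    mesh: DT2Mesh | None = None,
    source: str = "voxel",
) -> DT2Spectrum:
    """Solve min ||K f - s||^2 + lambda^2 ||f||^2 subject to f >= 0.

    Implemented as plain NNLS on the Tikhonov-augmented system
    [K; lambda I] f = [s; 0].  Deterministic; returns the raw
    (unnormalized) spectrum.
    """
    mesh = mesh or DT2Mesh()
    series = np.asarray(series, float).ravel()
    if kernel.shape != (series.size, mesh.size):
        raise GridMismatchError(
            f"kernel shape {kernel.shape} incompatible with series length "
            f"{series.size} and mesh size {mesh.size}"
        )
    if lambda_reg is None:
        lambda_reg = default_lambda(kernel)
    if lambda_reg < 0:
        raise RenalDwiError("lambda_reg must be non-negative")
    if np.all(series == 0):
        warnings.warn("all-zero signal: returning a zero spectrum", stacklevel=2)
        return DT2Spectrum(np.zeros(mesh.shape), mesh, source)
    if lambda_reg > 0:
        aug = np.vstack([kernel, lambda_reg * np.eye(mesh.size)])
        rhs = np.concatenate([series, np.zeros(mesh.size)])
    else:
        aug, rhs = kernel, series
    sol, _ = nnls(aug, rhs, maxiter=10 * mesh.size)
    return DT2Spectrum(sol.reshape(mesh.shape), mesh, source)


def _pick_boundary(candidates: np.ndarray, marginal: np.ndarray, window: tuple[float, float]) -> float:
    """Gridline inside ``window`` minimizing ``marginal``; ties break toward
    the arithmetic window midpoint."""
    lo, hi = window
    inside = np.flatnonzero((candidates >= lo) & (candidates <= hi))
    if inside.size == 0:
        raise RenalDwiError(f"no gridline inside boundary window {window}")
    vals = marginal[inside]
    best = vals.min()
    tied = inside[np.abs(vals - best) <= 1e-12 * max(1.0, abs(best))]
    midpoint = 0.5 * (lo + hi)
    return float(candidates[tied[np.argmin(np.abs(candidates[tied] - midpoint))]])


def choose_boundaries(
    spectrum: DT2Spectrum,
    t2_window: tuple[float, float] = (30.0, 50.0),
    d_window: tuple[float, float] = (6.0, 9.0),
) -> CompartmentPartition:
    """Automated stand-in for the manual peak-gap boundary choice.

    The D boundary is the mesh gridline inside ``d_window`` with minimal
    D-marginal intensity; the T2 boundary is the gridline inside
    ``t2_window`` minimizing the T2-marginal computed over the low-D
    (D <= d_boundary) part of the mesh.  Ties break toward the window
    midpoint, so a flat spectrum yields midpoint boundaries.
    """
    intensity = spectrum.intensity
    if spectrum.total_mass <= 0:
        raise RenalDwiError("cannot place boundaries on a zero spectrum")
    mesh = spectrum.mesh
    d_marginal = intensity.sum(axis=1)
    d_boundary = _pick_boundary(mesh.d, d_marginal, d_window)
    low_d = mesh.d <= d_boundary
    t2_marginal = intensity[low_d, :].sum(axis=0)
    t2_boundary = _pick_boundary(mesh.t2, t2_marginal, t2_window)
    return CompartmentPartition(mesh=mesh, d_boundary=d_boundary, t2_boundary=t2_boundary)


def compartment_fractions(
    spectrum: DT2Spectrum, partition: CompartmentPartition
) -> FractionTriple:
    """Volume fractions: compartment mass over total spectral mass."""
    if partition.mesh != spectrum.mesh:
        raise GridMismatchError("partition and spectrum use different meshes")
    total = spectrum.total_mass
    if total <= 0:
        raise RenalDwiError("cannot compute fractions of a zero-mass spectrum")
    masks = partition.masks()
    v = {x: float(spectrum.intensity[masks[x]].sum()) / total for x in COMPARTMENTS}
    return FractionTriple(v_a=v["A"], v_b=v["B"], v_c=v["C"])
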
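"""Corticomedullary-difference (CMD) biomarkers.

Scalar CMDs are plain differences of ROI means (cortex minus medulla).
The spectral CMD (dQ) acts on the cortex-minus-medulla *normalized* D-T2
difference spectrum: the signed difference is multiplied pointwise by a
compartmental filter and an order operator (a per-mesh-point weight), and
summed.  With constant weights the spectral CMD reduces exactly to the
fraction CMD (dV) of the same compartment; the default order weights are
the 1-based mesh index along the compartment's defining axis (T2 for B,
D for C), which makes dQ sensitive to peak position as well as mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, RenalDwiError
from .phantom import PhantomLabelMap
from .fitting import ParameterMap
from .spectrum import CompartmentPartition, DT2Mesh, DT2Spectrum

__all__ = [
    "RegionSummary",
    "SpectralOperator",
    "summarize_region",
    "cmd",
    "difference_spectrum",
    "spectral_cmd",
    "default_operator",
    "roi_spectrum",
]


@dataclass(frozen=True)
class RegionSummary:
    """Mean of a parameter map over the finite voxels of one region."""

    region: str
    parameter: str
    mean: float
    n_valid: int
    n_total: int
    volume_mm3: float


@dataclass(frozen=True)
class SpectralOperator:
    """Compartmental filter plus order weights for the spectral CMD."""

    mesh: DT2Mesh
    filter_mask: np.ndarray          # bool, mesh shape
    weights: np.ndarray              # float, mesh shape
    name: str = "custom"

    def __post_init__(self) -> None:
        mask = np.asarray(self.filter_mask, bool)
        w = np.asarray(self.weights, float)
        if mask.shape != self.mesh.shape or w.shape != self.mesh.shape:
            raise GridMismatchError("operator masks/weights must match the mesh shape")
        if not np.all(np.isfinite(w)):
            raise RenalDwiError("order weights must be finite")
        object.__setattr__(self, "filter_mask", mask)
        object.__setattr__(self, "weights", w)

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "n_filter_points": int(self.filter_mask.sum()),
            "weight_min": float(self.weights[self.filter_mask].min()),
            "weight_max": float(self.weights[self.filter_mask].max()),
        }


def summarize_region(
    pmap: ParameterMap, labels: PhantomLabelMap, region: str
) -> RegionSummary:
    """NaN-excluded arithmetic mean of a parameter map over one region."""
    mask = labels.mask(region)
    if pmap.data.shape != mask.shape:
        raise GridMismatchError(
            f"map grid {pmap.data.shape} does not match label grid {mask.shape}"
        )
    values = pmap.data[mask]
    if values.size == 0:
        raise RenalDwiError(f"region {region!r} is empty")
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise RenalDwiError(f"region {region!r} has no valid (finite) voxels")
    voxel_mm3 = float(np.prod(labels.voxel_size_mm))
    return RegionSummary(
        region=region,
        parameter=pmap.name,
        mean=float(finite.mean()),
        n_valid=int(finite.size),
        n_total=int(values.size),
        volume_mm3=voxel_mm3 * values.size,
    )


def cmd(cortex: RegionSummary, medulla: RegionSummary) -> float:
    """Scalar corticomedullary difference: cortical mean minus medullary mean."""
    if cortex.parameter != medulla.parameter:
        raise RenalDwiError(
            f"parameter mismatch: {cortex.parameter!r} vs {medulla.parameter!r}"
        )
    return cortex.mean - medulla.mean


def difference_spectrum(cortex: DT2Spectrum, medulla: DT2Spectrum) -> np.ndarray:
    """Signed mesh array: normalized cortical spectrum minus normalized
    medullary spectrum.  Sums to zero by construction."""
    if cortex.mesh != medulla.mesh:
        raise GridMismatchError("cortex and medulla spectra use different meshes")
    return cortex.normalized().intensity - medulla.normalized().intensity


def spectral_cmd(delta: np.ndarray, op: SpectralOperator) -> float:
    """dQ = sum over the filtered mesh of weight * difference intensity."""
    delta = np.asarray(delta, float)
    if delta.shape != op.mesh.shape:
        raise GridMismatchError(
            f"difference spectrum shape {delta.shape} != operator mesh {op.mesh.shape}"
        )
    return float(np.sum(op.weights[op.filter_mask] * delta[op.filter_mask]))


def default_operator(
    partition: CompartmentPartition, compartment: str, kind: str = "index_ramp"
) -> SpectralOperator:
    """Order operators for compartments B and C (A available on request).

    ``index_ramp`` (default): weight = 1-based mesh index along the
    compartment's defining axis — the T2 axis for B (T2-defined), the D
    axis for C (D-defined).  ``constant``: weight = 1 everywhere, which
    makes the spectral CMD equal the fraction CMD.  ``log_coordinate``:
    weight = natural log of the defining-axis coordinate.
    """
    mesh = partition.mesh
    masks = partition.masks()
    if compartment not in masks:
        raise RenalDwiError(f"unknown compartment {compartment!r}")
    axis = "t2" if compartment == "B" else "d"   # A is also T2-defined
    if kind == "constant":
        weights = np.ones(mesh.shape)
    elif kind == "index_ramp":
        if axis == "t2":
            weights = np.broadcast_to(
                np.arange(1, mesh.n_t2 + 1, dtype=float)[None, :], mesh.shape
            ).copy()
        else:
            weights = np.broadcast_to(
                np.arange(1, mesh.n_d + 1, dtype=float)[:, None], mesh.shape
            ).copy()
    elif kind == "log_coordinate":
        coord = mesh.t2 if axis == "t2" else mesh.d
        vec = np.log(coord)
        weights = (
            np.broadcast_to(vec[None, :], mesh.shape).copy()
            if axis == "t2"
            else np.broadcast_to(vec[:, None], mesh.shape).copy()
        )
    else:
        raise RenalDwiError(f"unknown operator kind {kind!r}")
    return SpectralOperator(
        mesh=mesh,
        filter_mask=masks[compartment],
        weights=weights,
        name=f"{kind}_{compartment}",
    )


def roi_spectrum(
    voxel_spectra: list[DT2Spectrum] | None = None,
    *,
    mean_signal: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
    lambda_reg: float | None = None,
    mesh: DT2Mesh | None = None,
    mode: str = "mean_of_spectra",
) -> DT2Spectrum:
    """ROI-level D-T2 spectrum.

    Default (``mean_of_spectra``): mass-weighted mean of per-voxel spectra,
    i.e. the voxel spectra are summed and the result normalized downstream.
    Alternative (``mean_signal``): invert the ROI-mean signal directly;
    requires ``mean_signal`` and ``kernel``.
    """
    from .spectrum import invert_spectrum  # local import avoids a cycle

    if mode == "mean_of_spectra":
        if not voxel_spectra:
            raise RenalDwiError("mean_of_spectra mode needs at least one voxel spectrum")
        mesh0 = voxel_spectra[0].mesh
        total = np.zeros(mesh0.shape)
        for sp in voxel_spectra:
            if sp.mesh != mesh0:
                raise GridMismatchError("voxel spectra use different meshes")
            total += sp.intensity
        return DT2Spectrum(total / len(voxel_spectra), mesh0, source="roi")
    if mode == "mean_signal":
        if mean_signal is None or kernel is None:
            raise RenalDwiError("mean_signal mode needs mean_signal and kernel")
        sp = invert_spectrum(mean_signal, kernel, lambda_reg=lambda_reg, mesh=mesh)
        return DT2Spectrum(sp.intensity, sp.mesh, source="roi")
    raise RenalDwiError(f"unknown roi_spectrum mode {mode!r}")
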
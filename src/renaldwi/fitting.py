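"""Voxel-wise parameter estimation from the multi-b diffusion series.

Three estimators, mirroring standard renal DWI practice:

* ``fit_adc`` — two-point mono-exponential ADC from the b=0 and b=800
  images only.
* ``fit_ivim_segmented`` — segmented IVIM over b <= 800 s/mm^2 with the
  threshold at 200 s/mm^2: a weighted log-linear fit of the high-b tail
  gives the tissue diffusivity D and, via the intercept, the perfusion
  fraction f; the pseudo-diffusion coefficient D* is then fitted by
  bounded nonlinear least squares with D and f frozen.
* ``fit_dki`` — direction-averaged diffusion kurtosis model on
  200 <= b <= 2500, a quadratic regression of log-signal on b with a free
  intercept (b=0 is excluded from the range, so S0 is never assumed).

Estimates outside their physiological bounds are clipped and flagged,
never discarded silently; invalid voxels propagate as NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ProtocolError
from .protocol import B_SCALE
from .signal import ImageSeries

__all__ = [
    "AdcResult",
    "IvimResult",
    "DkiResult",
    "ParameterMap",
    "IVIM_BOUNDS",
    "DKI_BOUNDS",
    "fit_adc",
    "fit_ivim_segmented",
    "fit_dki",
    "fit_volume",
]

logger = logging.getLogger(__name__)

# Physiological plausibility bounds (um^2/ms for diffusivities).
IVIM_BOUNDS = {"d": (0.1, 4.0), "d_star": (4.0, 300.0), "f": (0.0, 0.6)}
DKI_BOUNDS = {"md": (1e-6, np.inf), "mk": (0.0, 3.0)}

ADC_B_PAIR = (0.0, 800.0)
IVIM_B_MAX = 800.0
IVIM_THRESHOLD = 200.0
DKI_B_RANGE = (200.0, 2500.0)


@dataclass(frozen=True)
class AdcResult:
    adc: float                      # um^2/ms

    @property
    def valid(self) -> bool:
        return np.isfinite(self.adc)


@dataclass(frozen=True)
class IvimResult:
    d: float                        # um^2/ms
    d_star: float                   # um^2/ms
    f: float                        # fraction
    fit_flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return all(np.isfinite(v) for v in (self.d, self.d_star, self.f))


@dataclass(frozen=True)
class DkiResult:
    md: float                       # um^2/ms
    mk: float                       # dimensionless
    fit_flags: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return np.isfinite(self.md) and np.isfinite(self.mk)


@dataclass
class ParameterMap:
    """A fitted parameter over the image grid, with fit provenance."""

    name: str
    data: np.ndarray                # (nx, ny, nz), NaN outside mask / invalid
    units: str
    provenance: dict = field(default_factory=dict)

    @property
    def finite_fraction(self) -> float:
        return float(np.isfinite(self.data).mean())


def fit_adc(s0: float, s800: float, b: float = ADC_B_PAIR[1]) -> AdcResult:
    """Closed-form two-point ADC: ln(S0/Sb) / (b * 1e-3), in um^2/ms."""
    if not (np.isfinite(s0) and np.isfinite(s800)) or s0 <= 0 or s800 <= 0:
        return AdcResult(adc=float("nan"))
    return AdcResult(adc=float(np.log(s0 / s800) / (b * B_SCALE)))


def _clip_flag(value: float, lo: float, hi: float, name: str, flags: list[str]) -> float:
    if value < lo:
        flags.append(f"{name}_clipped_low")
        return lo
    if value > hi:
        flags.append(f"{name}_clipped_high")
        return hi
    return value


def fit_ivim_segmented(
    b: np.ndarray,
    signal: np.ndarray,
    threshold: float = IVIM_THRESHOLD,
    b_max: float = IVIM_B_MAX,
    s0_mode: str = "measured",
    step2_support: str = "all",
    n_avg: np.ndarray | None = None,
) -> IvimResult:
    """Two-step segmented IVIM fit on the b <= ``b_max`` points.

    Step 1: weighted log-linear regression over b >= ``threshold`` yields
    D and intercept A = S0(1-f); the weights are n_avg * signal^2, the
    Gauss-Markov variance correction for log-transformed magnitudes with
    per-point averaging (n_avg taken as 1 when not given).  f = 1 - A/S(0)
    with S(0) the measured b=0 signal (``s0_mode='extrapolate'`` uses a
    log-linear low-b extrapolation instead).  Step 2: with D and f frozen,
    D* is fitted by bounded nonlinear least squares, by default over all
    b <= ``b_max`` (``step2_support='low_b'`` restricts to b < threshold).
    """
    b = np.asarray(b, float)
    signal = np.asarray(signal, float)
    n_avg_arr = (
        np.ones_like(b) if n_avg is None
        else np.broadcast_to(np.asarray(n_avg, float), b.shape).copy()
    )
    sel = (b <= b_max) & np.isfinite(signal)
    b, signal, n_avg_arr = b[sel], signal[sel], n_avg_arr[sel]
    if np.any(signal <= 0) or b.size == 0 or np.all(signal == 0):
        return IvimResult(float("nan"), float("nan"), float("nan"), ("invalid_signal",))
    high = b >= threshold
    low = b < threshold
    if high.sum() < 3 or low.sum() < 3:
        raise FitError(
            f"segmented IVIM needs >= 3 points on each side of the {threshold} "
            f"s/mm^2 threshold (got {int(low.sum())} low, {int(high.sum())} high)"
        )
    flags: list[str] = []

    # Step 1: weighted log-linear tail fit.
    w = n_avg_arr[high] * signal[high] ** 2
    design = np.column_stack([np.ones(high.sum()), -b[high] * B_SCALE])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], np.log(signal[high]) * sw, rcond=None)
    intercept, d = float(coef[0]), float(coef[1])
    d = _clip_flag(d, *IVIM_BOUNDS["d"], "d", flags)

    if s0_mode == "measured":
        if not np.any(b == 0):
            raise FitError("s0_mode='measured' requires a b=0 point")
        s_zero = float(signal[b == 0].mean())
    elif s0_mode == "extrapolate":
        dl = np.column_stack([np.ones(low.sum()), -b[low] * B_SCALE])
        cl, *_ = np.linalg.lstsq(dl, np.log(signal[low]), rcond=None)
        s_zero = float(np.exp(cl[0]))
    else:
        raise FitError(f"unknown s0_mode {s0_mode!r}")

    f = 1.0 - float(np.exp(intercept)) / s_zero
    if not 0.0 <= f <= 1.0:
        f = min(max(f, 0.0), 1.0)
        flags.append("f_clipped_unit")
    f = _clip_flag(f, *IVIM_BOUNDS["f"], "f", flags)

    # Step 2: bounded 1-parameter fit of D*.
    if step2_support == "all":
        b2, s2 = b, signal
    elif step2_support == "low_b":
        b2, s2 = b[low], signal[low]
    else:
        raise FitError(f"unknown step2_support {step2_support!r}")

    def residual(p: np.ndarray) -> np.ndarray:
        model = s_zero * (
            f * np.exp(-b2 * p[0] * B_SCALE) + (1 - f) * np.exp(-b2 * d * B_SCALE)
        )
        return model - s2

    lo_ds = max(IVIM_BOUNDS["d_star"][0], d + 1e-6)
    sol = least_squares(
        residual, x0=np.array([min(max(20.0, lo_ds), IVIM_BOUNDS["d_star"][1])]),
        bounds=([lo_ds], [IVIM_BOUNDS["d_star"][1]]),
    )
    d_star = float(sol.x[0])
    if not sol.success:
        flags.append("dstar_no_convergence")
    if abs(d_star - lo_ds) < 1e-9 or abs(d_star - IVIM_BOUNDS["d_star"][1]) < 1e-9:
        flags.append("dstar_at_bound")
    return IvimResult(d=d, d_star=d_star, f=f, fit_flags=tuple(flags))


def fit_dki(b: np.ndarray, signal: np.ndarray, b_range: tuple[float, float] = DKI_B_RANGE) -> DkiResult:
    """Quadratic log-signal regression on ``b_range``:

    ln S = c0 - b (MD 1e-3) + (1/6) MK (MD 1e-3)^2 b^2

    with a free intercept c0 (S0 is not assumed).  MD = -c1/1e-3 and
    MK = 6 c2 / c1^2; noiseless kurtosis signals are recovered exactly.
    """
    b = np.asarray(b, float)
    signal = np.asarray(signal, float)
    sel = (b >= b_range[0]) & (b <= b_range[1]) & np.isfinite(signal)
    b, signal = b[sel], signal[sel]
    if b.size and np.any(signal <= 0):
        return DkiResult(float("nan"), float("nan"), ("invalid_signal",))
    if np.unique(b).size < 3:
        raise FitError(
            f"DKI needs >= 3 distinct b values in {b_range} (got {np.unique(b).size})"
        )
    x = b * B_SCALE
    design = np.column_stack([np.ones_like(x), -x, x**2 / 6.0])
    coef, *_ = np.linalg.lstsq(design, np.log(signal), rcond=None)
    md = float(coef[1])
    flags: list[str] = []
    if md <= 0:
        return DkiResult(float("nan"), float("nan"), ("nonpositive_md",))
    mk = float(coef[2]) / md**2
    md = _clip_flag(md, *DKI_BOUNDS["md"], "md", flags)
    mk = _clip_flag(mk, *DKI_BOUNDS["mk"], "mk", flags)
    return DkiResult(md=md, mk=mk, fit_flags=tuple(flags))


_MODEL_PARAMS = {
    "adc": (("adc", "um^2/ms"),),
    "ivim": (("ivim_d", "um^2/ms"), ("ivim_dstar", "um^2/ms"), ("ivim_f", "fraction")),
    "dki": (("dki_md", "um^2/ms"), ("dki_mk", "dimensionless")),
}


def _fit_voxel(model: str, b: np.ndarray, sig: np.ndarray, options: dict) -> tuple:
    if model == "adc":
        at0 = sig[b == ADC_B_PAIR[0]]
        at800 = sig[b == ADC_B_PAIR[1]]
        res = fit_adc(float(at0.mean()), float(at800.mean()))
        return (res.adc,), ()
    if model == "ivim":
        res = fit_ivim_segmented(b, sig, **options)
        return (res.d, res.d_star, res.f), res.fit_flags
    if model == "dki":
        res = fit_dki(b, sig, **options)
        return (res.md, res.mk), res.fit_flags
    raise FitError(f"unknown model {model!r}; one of {tuple(_MODEL_PARAMS)}")


def fit_volume(
    image: ImageSeries,
    mask: np.ndarray,
    model: str,
    **options,
) -> dict[str, ParameterMap]:
    """Apply a per-voxel fit to every masked voxel of a 4-D series.

    Returns one ParameterMap per fitted parameter; voxels outside the mask
    (or with invalid signal) are NaN.  The count of flagged voxels is
    recorded in each map's provenance and logged.
    """
    if model not in _MODEL_PARAMS:
        raise FitError(f"unknown model {model!r}; one of {tuple(_MODEL_PARAMS)}")
    b = image.protocol.b
    _check_protocol_support(model, b)
    mask = np.asarray(mask, bool)
    if mask.shape != image.grid_shape:
        raise FitError(
            f"mask shape {mask.shape} does not match image grid {image.grid_shape}"
        )
    if model == "ivim" and "n_avg" not in options:
        options = {**options, "n_avg": image.protocol.n_avg}
    params = _MODEL_PARAMS[model]
    out = {name: np.full(image.grid_shape, np.nan) for name, _ in params}
    n_flagged = 0
    idx = np.argwhere(mask)
    if idx.size == 0:
        warnings.warn("empty mask: returning all-NaN maps", stacklevel=2)
    for ix, iy, iz in idx:
        values, flags = _fit_voxel(model, b, image.data[ix, iy, iz, :], options)
        if flags:
            n_flagged += 1
        for (name, _), val in zip(params, values):
            out[name][ix, iy, iz] = val
    logger.info("fit_volume(%s): %d voxels, %d flagged", model, len(idx), n_flagged)
    def _jsonable(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    provenance = {
        "model": model,
        "protocol": image.protocol.name,
        "options": {k: _jsonable(v) for k, v in options.items()},
        "n_voxels": int(len(idx)),
        "n_flagged": int(n_flagged),
    }
    return {
        name: ParameterMap(name=name, data=out[name], units=units, provenance=dict(provenance))
        for name, units in params
    }


def _check_protocol_support(model: str, b: np.ndarray) -> None:
    if model == "adc" and not (np.any(b == ADC_B_PAIR[0]) and np.any(b == ADC_B_PAIR[1])):
        raise ProtocolError("ADC fit requires b=0 and b=800 s/mm^2 in the protocol")
    if model == "ivim":
        low = ((b < IVIM_THRESHOLD)).sum()
        high = ((b >= IVIM_THRESHOLD) & (b <= IVIM_B_MAX)).sum()
        if low < 3 or high < 3:
            raise ProtocolError("protocol lacks the b coverage for segmented IVIM")
    if model == "dki" and np.unique(b[(b >= DKI_B_RANGE[0]) & (b <= DKI_B_RANGE[1])]).size < 3:
        raise ProtocolError("protocol lacks >= 3 distinct b in the DKI range")
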
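"""Acquisition protocols for multi-b and multi-TE-multi-b renal DWI.

Two protocols are built in:

``multi_b_12``
    Spin-echo EPI diffusion series at a single echo time (54 ms) with
    13 b values from 0 to 2500 s/mm^2.  Higher b values are acquired with
    more signal averages (up to 6 at b = 2500) to compensate for the
    decaying SNR.

``drcsi_6x6``
    The diffusion-relaxation protocol: every combination of six echo
    times (51-200 ms) and six b values (0-1500 s/mm^2), 36 acquisitions,
    one average each.  Sampling both dimensions is what makes the D-T2
    spectrum inversion identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError

__all__ = ["AcquisitionProtocol", "make_protocol", "PROTOCOL_NAMES"]

#: Conversion so that b [s/mm^2] times D [um^2/ms] becomes dimensionless.
B_SCALE = 1.0e-3


@dataclass(frozen=True)
class AcquisitionProtocol:
    """An ordered list of (b, TE, n_avg) acquisition points."""

    name: str
    b: np.ndarray          # s/mm^2
    te: np.ndarray         # ms
    n_avg: np.ndarray      # positive ints

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        te = np.asarray(self.te, dtype=float)
        n_avg = np.asarray(self.n_avg, dtype=int)
        if not (b.shape == te.shape == n_avg.shape) or b.ndim != 1:
            raise ProtocolError("b, te and n_avg must be 1-D arrays of equal length")
        if np.any(b < 0):
            raise ProtocolError("b values must be non-negative")
        if np.any(te <= 0):
            raise ProtocolError("echo times must be positive")
        if np.any(n_avg < 1):
            raise ProtocolError("n_avg must be a positive integer per point")
        if np.unique(b).size < 2:
            raise ProtocolError("a protocol needs at least 2 distinct b values")
        pairs = set(zip(b.tolist(), te.tolist()))
        if len(pairs) != b.size:
            raise ProtocolError("(b, te) pairs must be unique")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "n_avg", n_avg)

    def __len__(self) -> int:
        return int(self.b.size)

    @property
    def n_distinct_te(self) -> int:
        return int(np.unique(self.te).size)

    def to_table(self) -> list[dict]:
        """Sidecar-friendly list of per-volume acquisition entries."""
        return [
            {"b_s_mm2": float(b), "te_ms": float(t), "n_avg": int(n)}
            for b, t, n in zip(self.b, self.te, self.n_avg)
        ]

    @classmethod
    def from_table(cls, name: str, table: list[dict]) -> "AcquisitionProtocol":
        return cls(
            name=name,
            b=np.array([row["b_s_mm2"] for row in table], float),
            te=np.array([row["te_ms"] for row in table], float),
            n_avg=np.array([row["n_avg"] for row in table], int),
        )


_MULTI_B = np.array(
    [0, 10, 30, 50, 70, 100, 200, 400, 800, 1000, 1500, 2000, 2500], float
)
_MULTI_B_AVG = np.array([1, 1, 1, 1, 1, 1, 1, 1, 2, 3, 4, 5, 6], int)
_MULTI_B_TE = 54.0

_DRCSI_TE = np.array([51, 80, 110, 140, 180, 200], float)
_DRCSI_B = np.array([0, 150, 400, 800, 1200, 1500], float)

PROTOCOL_NAMES = ("multi_b_12", "drcsi_6x6")


def make_protocol(name: str) -> AcquisitionProtocol:
    """Return one of the built-in acquisition protocols by name."""
    if name == "multi_b_12":
        return AcquisitionProtocol(
            name=name,
            b=_MULTI_B.copy(),
            te=np.full_like(_MULTI_B, _MULTI_B_TE),
            n_avg=_MULTI_B_AVG.copy(),
        )
    if name == "drcsi_6x6":
        bb, tt = np.meshgrid(_DRCSI_B, _DRCSI_TE, indexing="ij")
        return AcquisitionProtocol(
            name=name,
            b=bb.ravel(),
            te=tt.ravel(),
            n_avg=np.ones(bb.size, int),
        )
    raise ProtocolError(
        f"unknown protocol {name!r}; available: {', '.join(PROTOCOL_NAMES)}"
    )
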
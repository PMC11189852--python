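"""Run configuration: a fully serializable description of one pipeline run.

Every stochastic stage derives from the single mandatory ``seed``; a
config without a seed is rejected so that no run is silently
irreproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .cohort import DEFAULT_COHORT_PARAMS
from .errors import ConfigError
from .phantom import PhantomGeometry
from .pipeline import AnalysisOptions

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int
    output_dir: str = "results"
    n_per_group: tuple[int, int] = (23, 19)
    protocols: tuple[str, ...] = ("multi_b_12", "drcsi_6x6")
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_PARAMS))
    save_images: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        d["analysis"] = asdict(self.analysis)
        return d


def _coerce_tuple(value, n, what):
    try:
        out = tuple(value)
    except TypeError as exc:
        raise ConfigError(f"{what} must be a sequence of length {n}") from exc
    if len(out) != n:
        raise ConfigError(f"{what} must have length {n}")
    return out


def load_config(data: dict | str | Path) -> RunConfig:
    """Build a RunConfig from a dict or a YAML file path; schema-checked."""
    if not isinstance(data, dict):
        from .io import load_yaml

        data = load_yaml(data)
    if "seed" not in data:
        raise ConfigError("config must set an explicit integer 'seed'")
    if not isinstance(data["seed"], int):
        raise ConfigError("'seed' must be an integer")
    known = {
        "seed", "output_dir", "n_per_group", "protocols", "geometry",
        "analysis", "group_params", "save_images",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {"seed": data["seed"]}
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    if "n_per_group" in data:
        kwargs["n_per_group"] = tuple(
            int(n) for n in _coerce_tuple(data["n_per_group"], 2, "n_per_group")
        )
    if "protocols" in data:
        kwargs["protocols"] = tuple(data["protocols"])
    if "geometry" in data:
        geo = dict(data["geometry"])
        for key in ("outer_semiaxes", "voxel_size_mm"):
            if key in geo:
                geo[key] = tuple(geo[key])
        try:
            kwargs["geometry"] = PhantomGeometry(**geo)
        except TypeError as exc:
            raise ConfigError(f"bad geometry block: {exc}") from exc
    if "analysis" in data:
        ana = dict(data["analysis"])
        for key in ("t2_window", "d_window"):
            if key in ana:
                ana[key] = tuple(ana[key])
        try:
            kwargs["analysis"] = AnalysisOptions(**ana)
        except TypeError as exc:
            raise ConfigError(f"bad analysis block: {exc}") from exc
    if "group_params" in data:
        kwargs["group_params"] = dict(data["group_params"])
    if "save_images" in data:
        kwargs["save_images"] = bool(data["save_images"])
    return RunConfig(**kwargs)
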
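"""Synthetic CKD cohort generator with fibrosis-group structure.

Subjects belong to a ``mild`` (IF score 1) or ``moderate_severe`` (IF 2-3)
interstitial-fibrosis group.  Group differences are placed in the
ground-truth tissue parameters (perfusion fraction, tissue diffusivity,
kurtosis, D-T2 component weights) and in the clinical eGFR distribution,
never in fitted outputs, so the full fitting pipeline is exercised
end-to-end.

Calibration of the default ground-truth table
---------------------------------------------
The forward model has a single tissue diffusivity per region, so the
fitted DKI mean diffusivity equals the generating D exactly while the
two-point ADC is a deterministic function of (D, f, MK).  ADC, IVIM-D and
MD therefore cannot all be assigned independent group distributions.  The
defaults anchor, in each region, the statistic with the most constraining
published group contrast: cortical D is anchored to the cortical MD
distribution (strongly separated between groups), and medullary D is
solved so that the *derived* ADC reproduces the medullary ADC
distribution (a borderline, non-significant contrast that would otherwise
be distorted by the perfusion-fraction difference).  f, D*, MK and the
compartment weights are taken directly from their published group
means and SDs.  Ground-truth draws are independent truncated (clipped)
normals per field.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import RenalDwiError
from .phantom import PhantomGeometry, PhantomLabelMap, build_phantom
from .protocol import B_SCALE, make_protocol
from .signal import ImageSeries, TissueGroundTruth, add_rician_noise, forward_signal
from .spectrum import DT2Mesh
from .stats import creatinine_for_egfr, egfr_ckd_epi

__all__ = [
    "SyntheticSubjectSpec",
    "SubjectSim",
    "Cohort",
    "DEFAULT_COHORT_PARAMS",
    "DEFAULT_SEED",
    "default_cohort_params",
    "derived_two_point_adc",
    "solve_d_for_adc",
    "simulate_cohort",
]

DEFAULT_SEED = 42
GROUPS = ("mild", "moderate_severe")
DEFAULT_NOISE_SIGMA = {"multi_b_12": 20.0, "drcsi_6x6": 10.0}
DEFAULT_S0 = 1000.0

# Nominal (D um^2/ms, T2 ms) positions of the three spectral components;
# snapped to the nearest mesh point at generation time.  A sits below the
# 30-50 ms T2 boundary window but short enough TEs (>= 51 ms) still see it;
# a much shorter T2 would be invisible to the protocol.
DEFAULT_COMPONENT_POSITIONS = {"A": (1.2, 26.0), "B": (1.5, 90.0), "C": (15.0, 70.0)}

ADC_B = 800.0

# Published group statistics used as the generator's study conditions
# (mean, SD); fractions as fractions, diffusivities in um^2/ms.
_PRINTED = {
    "mild": {
        "egfr": (90.3, 19.7),
        "cortex": {
            "f_perf": (0.226, 0.046),
            "d_star": (73.0, 20.3),
            "mk": (0.492, 0.029),
            "md_anchor": (3.17, 0.29),
            "weights": {"A": (0.260, 0.073), "B": (0.429, 0.085), "C": (0.310, 0.065)},
        },
        "medulla": {
            "f_perf": (0.161, 0.042),
            "d_star": (53.1, 19.5),
            "mk": (0.483, 0.059),
            "adc_anchor": (1.85, 0.12),
            "weights": {"A": (0.257, 0.049), "B": (0.501, 0.083), "C": (0.243, 0.058)},
        },
    },
    "moderate_severe": {
        "egfr": (51.1, 24.7),
        "cortex": {
            "f_perf": (0.173, 0.049),
            "d_star": (77.9, 26.6),
            "mk": (0.502, 0.040),
            "md_anchor": (2.74, 0.48),
            "weights": {"A": (0.209, 0.083), "B": (0.545, 0.084), "C": (0.249, 0.053)},
        },
        "medulla": {
            "f_perf": (0.121, 0.033),
            "d_star": (67.4, 17.1),
            "mk": (0.487, 0.057),
            "adc_anchor": (1.78, 0.16),
            "weights": {"A": (0.236, 0.087), "B": (0.549, 0.094), "C": (0.220, 0.055)},
        },
    },
}

_AGE = (49.0, 14.0)          # years; same in both groups
_MALE_FRACTION = 23.0 / 42.0  # same in both groups
_IF_SCORE_WEIGHTS = {"mild": {1: 1.0}, "moderate_severe": {2: 13 / 19, 3: 6 / 19}}

# Clip bounds for the truncated-normal ground-truth draws.
_CLIP = {
    "f_perf": (0.01, 0.6),
    "d_tissue": (0.3, 4.0),
    "d_star": (10.0, 300.0),
    "mk": (0.0, 3.0),
    "weight": (0.01, 1.0),
    "egfr": (5.0, 150.0),
    "age": (18.0, 80.0),
}


def derived_two_point_adc(d: float, f: float, mk: float, d_star: float) -> float:
    """ADC that the b0/b800 two-point fit recovers from the noiseless
    IVIM+kurtosis forward model."""
    bd = ADC_B * d * B_SCALE
    s_ratio = f * np.exp(-ADC_B * d_star * B_SCALE) + (1 - f) * np.exp(-bd + mk * bd**2 / 6)
    return float(-np.log(s_ratio) / (ADC_B * B_SCALE))


def solve_d_for_adc(target_adc: float, f: float, mk: float, d_star: float) -> float:
    """Tissue diffusivity whose derived two-point ADC equals ``target_adc``."""
    fn = lambda d: derived_two_point_adc(d, f, mk, d_star) - target_adc
    return float(brentq(fn, 0.2, 5.0, xtol=1e-10))


def _adc_sensitivities(d: float, f: float, mk: float, d_star: float) -> tuple[float, float]:
    """Numeric partial derivatives of the derived ADC wrt (d, f)."""
    eps = 1e-6
    c_d = (derived_two_point_adc(d + eps, f, mk, d_star)
           - derived_two_point_adc(d - eps, f, mk, d_star)) / (2 * eps)
    c_f = (derived_two_point_adc(d, f + eps, mk, d_star)
           - derived_two_point_adc(d, f - eps, mk, d_star)) / (2 * eps)
    return c_d, c_f


def default_cohort_params() -> dict:
    """Build the default per-group distribution table.

    Returns a nested dict: group -> region -> field -> (mean, sd), plus
    clinical entries.  The d_tissue rows are derived from the anchors as
    described in the module docstring.
    """
    params: dict = {"component_positions": dict(DEFAULT_COMPONENT_POSITIONS),
                    "noise_sigma": dict(DEFAULT_NOISE_SIGMA),
                    "s0": DEFAULT_S0,
                    "age": _AGE,
                    "male_fraction": _MALE_FRACTION,
                    "groups": {}}
    for group, spec in _PRINTED.items():
        gp: dict = {"egfr": spec["egfr"], "regions": {}}
        for region in ("cortex", "medulla"):
            rs = spec[region]
            f_mean, f_sd = rs["f_perf"]
            mk_mean, _ = rs["mk"]
            ds_mean, _ = rs["d_star"]
            if "md_anchor" in rs:
                d_mean, d_sd = rs["md_anchor"]
            else:
                adc_mean, adc_sd = rs["adc_anchor"]
                d_mean = solve_d_for_adc(adc_mean, f_mean, mk_mean, ds_mean)
                c_d, c_f = _adc_sensitivities(d_mean, f_mean, mk_mean, ds_mean)
                # Allocate the printed ADC variance between the D and f draws.
                var_from_f = (c_f * f_sd) ** 2
                var_d = max(adc_sd**2 - var_from_f, (0.25 * adc_sd) ** 2)
                d_sd = float(np.sqrt(var_d) / abs(c_d))
            gp["regions"][region] = {
                "f_perf": rs["f_perf"],
                "d_tissue": (float(d_mean), float(d_sd)),
                "d_star": rs["d_star"],
                "mk": rs["mk"],
                "weights": {k: tuple(v) for k, v in rs["weights"].items()},
            }
        params["groups"][group] = gp
    return params


DEFAULT_COHORT_PARAMS = default_cohort_params()


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Clinical fields plus per-region ground truth for one subject."""

    subject_id: str
    group: str
    if_score: int
    age: float
    sex: str
    serum_creatinine: float     # mg/dL
    egfr: float                 # mL/min/1.73 m^2
    cortex: TissueGroundTruth
    medulla: TissueGroundTruth
    noise_sigma: dict
    seed: int

    def __post_init__(self) -> None:
        if self.if_score not in (1, 2, 3):
            raise RenalDwiError("if_score must be 1, 2 or 3")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise RenalDwiError("noise_sigma must be non-negative")
        if (self.group == "mild") != (self.if_score == 1):
            raise RenalDwiError("group 'mild' corresponds exactly to IF score 1")


@dataclass
class SubjectSim:
    spec: SyntheticSubjectSpec
    images: dict[str, ImageSeries] = field(default_factory=dict)


@dataclass
class Cohort:
    subjects: list[SubjectSim]
    labels: PhantomLabelMap
    params: dict
    seed: int

    def clinical_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.spec.subject_id,
                "group": s.spec.group,
                "if_score": s.spec.if_score,
                "age": s.spec.age,
                "sex": s.spec.sex,
                "serum_creatinine_mg_dl": s.spec.serum_creatinine,
                "egfr": s.spec.egfr,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.spec.subject_id, "group": s.spec.group}
            for region in ("cortex", "medulla"):
                gt: TissueGroundTruth = getattr(s.spec, region)
                row[f"{region}_f_perf"] = gt.f_perf
                row[f"{region}_d_tissue"] = gt.d_tissue
                row[f"{region}_d_star"] = gt.d_star
                row[f"{region}_mk"] = gt.mk
                for comp, (_, _, w) in zip(("A", "B", "C"), gt.spectrum_components):
                    row[f"{region}_w_{comp.lower()}"] = w
            rows.append(row)
        return pd.DataFrame(rows)


def _clip_normal(rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]) -> float:
    if sd < 0:
        raise RenalDwiError("distribution SD must be non-negative")
    return float(np.clip(rng.normal(mean, sd), *bounds))


def _draw_ground_truth(
    rng: np.random.Generator, region_params: dict, positions: dict, s0: float
) -> TissueGroundTruth:
    f = _clip_normal(rng, *region_params["f_perf"], _CLIP["f_perf"])
    d = _clip_normal(rng, *region_params["d_tissue"], _CLIP["d_tissue"])
    d_star = _clip_normal(rng, *region_params["d_star"], _CLIP["d_star"])
    if d_star <= d:
        d_star = d + 5.0
    mk = _clip_normal(rng, *region_params["mk"], _CLIP["mk"])
    raw_w = {
        comp: _clip_normal(rng, *region_params["weights"][comp], _CLIP["weight"])
        for comp in ("A", "B", "C")
    }
    total = sum(raw_w.values())
    components = tuple(
        (positions[comp][0], positions[comp][1], raw_w[comp] / total)
        for comp in ("A", "B", "C")
    )
    return TissueGroundTruth(
        f_perf=f, d_tissue=d, d_star=d_star, mk=mk,
        spectrum_components=components, s0=s0,
    )


def _snapped_positions(positions: dict, mesh: DT2Mesh) -> dict:
    out = {}
    for comp, (d, t2) in positions.items():
        j, k = mesh.nearest(d, t2)
        out[comp] = (float(mesh.d[j]), float(mesh.t2[k]))
    return out


def _render_subject_images(
    spec: SyntheticSubjectSpec,
    labels: PhantomLabelMap,
    protocols: tuple[str, ...],
    rng: np.random.Generator,
) -> dict[str, ImageSeries]:
    images = {}
    model_for = {"multi_b_12": "ivim_kurtosis", "drcsi_6x6": "dt2"}
    for pname in protocols:
        protocol = make_protocol(pname)
        vol = np.zeros(labels.labels.shape + (len(protocol),))
        for region in ("cortex", "medulla"):
            gt = getattr(spec, region)
            sig = forward_signal(gt, protocol, model_for[pname])
            vol[labels.mask(region), :] = sig
        noisy = add_rician_noise(
            vol.reshape(-1, len(protocol)),
            sigma=spec.noise_sigma[pname],
            n_avg=protocol.n_avg,
            seed=rng,
        ).reshape(vol.shape)
        images[pname] = ImageSeries(
            data=noisy, protocol=protocol, voxel_size_mm=labels.voxel_size_mm
        )
    return images


def simulate_cohort(
    group_params: dict | None = None,
    n_per_group: tuple[int, int] = (23, 19),
    seed: int = DEFAULT_SEED,
    geometry: PhantomGeometry | None = None,
    generate_images: bool = True,
    protocols: tuple[str, ...] = ("multi_b_12", "drcsi_6x6"),
    snap_components_to_mesh: bool = True,
) -> Cohort:
    """Draw a whole synthetic cohort: subject specs and (optionally) images.

    ``group_params`` defaults to the calibrated published-statistics table;
    ``n_per_group`` is (n_mild, n_moderate_severe).  Reproducible: the same
    seed yields byte-identical cohort tables and images.
    """
    params = copy.deepcopy(group_params or DEFAULT_COHORT_PARAMS)
    if any(n <= 0 for n in n_per_group):
        raise RenalDwiError("both groups must be non-empty")
    for group in GROUPS:
        for region_params in params["groups"][group]["regions"].values():
            for key in ("f_perf", "d_tissue", "d_star", "mk"):
                if region_params[key][1] < 0:
                    raise RenalDwiError(f"negative SD for {key}")
            for w in region_params["weights"].values():
                if w[1] < 0:
                    raise RenalDwiError("negative SD for a spectral weight")

    positions = params["component_positions"]
    if snap_components_to_mesh:
        positions = _snapped_positions(positions, DT2Mesh())
    labels = build_phantom(geometry)
    master = np.random.default_rng(seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=sum(n_per_group))

    subjects: list[SubjectSim] = []
    counter = 0
    for group, n in zip(GROUPS, n_per_group):
        gp = params["groups"][group]
        for _ in range(n):
            sub_seed = int(subject_seeds[counter])
            rng = np.random.default_rng(sub_seed)
            counter += 1
            scores, probs = zip(*_IF_SCORE_WEIGHTS[group].items())
            if_score = int(rng.choice(scores, p=probs))
            age = _clip_normal(rng, *params["age"], _CLIP["age"])
            sex = "M" if rng.random() < params["male_fraction"] else "F"
            egfr_target = _clip_normal(rng, *gp["egfr"], _CLIP["egfr"])
            scr = creatinine_for_egfr(egfr_target, age, sex)
            cortex = _draw_ground_truth(rng, gp["regions"]["cortex"], positions, params["s0"])
            medulla = _draw_ground_truth(rng, gp["regions"]["medulla"], positions, params["s0"])
            spec = SyntheticSubjectSpec(
                subject_id=f"sub-{counter:03d}",
                group=group,
                if_score=if_score,
                age=age,
                sex=sex,
                serum_creatinine=scr,
                egfr=egfr_ckd_epi(scr, age, sex),
                cortex=cortex,
                medulla=medulla,
                noise_sigma=dict(params["noise_sigma"]),
                seed=sub_seed,
            )
            images = (
                _render_subject_images(spec, labels, protocols, rng)
                if generate_images
                else {}
            )
            subjects.append(SubjectSim(spec=spec, images=images))
    return Cohort(subjects=subjects, labels=labels, params=params, seed=seed)
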
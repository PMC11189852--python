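"""Cohort-level result tables.

Produces the three result tables of the analysis on a per-subject wide
table: group comparison of every cortical / medullary / CMD parameter
(Mann-Whitney, with significance stars), per-marker ROC with Youden
cutoffs including cortical-value + CMD combinations, and multivariable
score models including eGFR combinations.  Group label encoding:
mild = 0, moderate_severe = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import RenalDwiError
from .stats import (
    GroupTestResult,
    auc_band,
    fit_score_model,
    group_compare,
    roc,
)

__all__ = [
    "MRI_PARAMETERS",
    "table3_group_comparison",
    "clinical_comparison",
    "table4_roc",
    "table5_models",
    "run_table_suite",
]

# parameter key -> (pretty name, units); column names are
# cortex_<key>, medulla_<key>, delta_<key> in the wide subject table.
MRI_PARAMETERS = {
    "adc": ("ADC", "um^2/ms"),
    "d": ("IVIM D", "um^2/ms"),
    "d_star": ("IVIM D*", "um^2/ms"),
    "f": ("IVIM f", "%"),
    "md": ("DKI MD", "um^2/ms"),
    "mk": ("DKI MK", ""),
    "v_a": ("DR-CSI V_A", "%"),
    "v_b": ("DR-CSI V_B", "%"),
    "v_c": ("DR-CSI V_C", "%"),
}

SPECTRAL_CMDS = {"q_b": "DR-CSI dQ_B", "q_c": "DR-CSI dQ_C"}

# Table-4 marker menu: key -> compartment-matched CMD column.
_TABLE4_MARKERS = ("adc", "d", "f", "md", "v_b", "v_c")
_TABLE4_SPECTRAL = {"q_b": "v_b", "q_c": "v_c"}   # dQ rows combine with this cortical marker

# Table-5 model menu (predictor column lists).
TABLE5_MODELS = {
    "V_B + ADC": ["cortex_v_b", "cortex_adc"],
    "V_B + f": ["cortex_v_b", "cortex_f"],
    "ADC + f": ["cortex_adc", "cortex_f"],
    "V_B + dADC": ["cortex_v_b", "delta_adc"],
    "V_B + ADC + f": ["cortex_v_b", "cortex_adc", "cortex_f"],
    "V_B + dADC + f": ["cortex_v_b", "delta_adc", "cortex_f"],
    "eGFR": ["egfr"],
    "eGFR + V_B + dADC": ["egfr", "cortex_v_b", "delta_adc"],
    "eGFR + V_B + f": ["egfr", "cortex_v_b", "cortex_f"],
}


def _require_groups(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mild = frame[frame["group"] == "mild"]
    msev = frame[frame["group"] == "moderate_severe"]
    if mild.empty or msev.empty:
        raise RenalDwiError("both fibrosis groups must be non-empty")
    return mild, msev


def _mean_sd(v: pd.Series) -> str:
    return f"{v.mean():.3g} +/- {v.std(ddof=1):.3g}"


def _compare_row(name: str, units: str, mild: pd.Series, msev: pd.Series) -> dict:
    res: GroupTestResult = group_compare(mild.to_numpy(), msev.to_numpy(), "mannwhitney")
    return {
        "parameter": name,
        "units": units,
        "mild": _mean_sd(mild),
        "moderate_severe": _mean_sd(msev),
        "mild_mean": mild.mean(),
        "moderate_severe_mean": msev.mean(),
        "p": res.p,
        "significance": res.stars,
    }


def table3_group_comparison(frame: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of every cortical, medullary and CMD parameter."""
    mild, msev = _require_groups(frame)
    rows = []
    for key, (pretty, units) in MRI_PARAMETERS.items():
        for scope, prefix in (("Cortical", "cortex"), ("Medullary", "medulla"), ("d", "delta")):
            col = f"{prefix}_{key}"
            rows.append(_compare_row(f"{scope} {pretty}", units, mild[col], msev[col]))
    for key, pretty in SPECTRAL_CMDS.items():
        col = f"delta_{key}"
        rows.append(_compare_row(pretty, "", mild[col], msev[col]))
    return pd.DataFrame(rows)


def clinical_comparison(frame: pd.DataFrame) -> pd.DataFrame:
    """Age (t), sex (chi-square) and eGFR (t) between the fibrosis groups."""
    mild, msev = _require_groups(frame)
    rows = []
    for col, kind in (("age", "t"), ("egfr", "t")):
        res = group_compare(mild[col].to_numpy(), msev[col].to_numpy(), kind)
        rows.append({
            "characteristic": col, "test": res.test,
            "mild": _mean_sd(mild[col]), "moderate_severe": _mean_sd(msev[col]),
            "p": res.p, "significance": res.stars,
        })
    counts_mild = [(mild["sex"] == "M").sum(), (mild["sex"] == "F").sum()]
    counts_msev = [(msev["sex"] == "M").sum(), (msev["sex"] == "F").sum()]
    res = group_compare(counts_mild, counts_msev, "chi2")
    rows.append({
        "characteristic": "sex", "test": res.test,
        "mild": f"{counts_mild[0]}M/{counts_mild[1]}F",
        "moderate_severe": f"{counts_msev[0]}M/{counts_msev[1]}F",
        "p": res.p, "significance": res.stars,
    })
    return pd.DataFrame(rows)


def _roc_fields(frame: pd.DataFrame, column: str) -> dict:
    res = roc(frame[column].to_numpy(), frame["label"].to_numpy())
    return {
        "auc": res.auc, "band": auc_band(res.auc), "orientation": res.orientation,
        "cutoff": res.cutoff, "specificity": res.specificity,
        "sensitivity": res.sensitivity, "youden_j": res.youden_j,
    }


def _combination_roc(frame: pd.DataFrame, predictors: list[str]) -> dict:
    model = fit_score_model(frame, predictors)
    scores = pd.DataFrame({"score": model.scores, "label": frame["label"].to_numpy()})
    out = _roc_fields(scores, "score")
    out["predictors"] = " + ".join(predictors)
    return out


def table4_roc(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-marker diagnostics: cortical value, CMD, and their combination."""
    _require_groups(frame)
    rows = []
    for key in _TABLE4_MARKERS:
        pretty, units = MRI_PARAMETERS[key]
        cortical = _roc_fields(frame, f"cortex_{key}")
        cmd_col = f"delta_{key}"
        cmd_roc = _roc_fields(frame, cmd_col)
        combo = _combination_roc(frame, [f"cortex_{key}", cmd_col])
        rows.append({
            "marker": pretty, "units": units,
            **{f"cortex_{k}": v for k, v in cortical.items()},
            **{f"cmd_{k}": v for k, v in cmd_roc.items()},
            **{f"combined_{k}": v for k, v in combo.items()},
        })
    for key, cortical_partner in _TABLE4_SPECTRAL.items():
        pretty = SPECTRAL_CMDS[key]
        cmd_roc = _roc_fields(frame, f"delta_{key}")
        combo = _combination_roc(frame, [f"cortex_{cortical_partner}", f"delta_{key}"])
        rows.append({
            "marker": pretty, "units": "",
            **{f"cortex_{k}": np.nan for k in cmd_roc},
            **{f"cmd_{k}": v for k, v in cmd_roc.items()},
            **{f"combined_{k}": v for k, v in combo.items()},
        })
    return pd.DataFrame(rows)


def table5_models(frame: pd.DataFrame) -> pd.DataFrame:
    """Multivariable linear score models (including eGFR combinations)."""
    _require_groups(frame)
    rows = []
    for name, predictors in TABLE5_MODELS.items():
        fields = _combination_roc(frame, predictors)
        rows.append({"model": name, **fields})
    return pd.DataFrame(rows)


def run_table_suite(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All cohort-level tables from one per-subject wide table."""
    if "label" not in frame.columns:
        frame = frame.assign(label=(frame["group"] == "moderate_severe").astype(int))
    return {
        "table3_group_comparison": table3_group_comparison(frame),
        "clinical_comparison": clinical_comparison(frame),
        "table4_roc": table4_roc(frame),
        "table5_models": table5_models(frame),
    }
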
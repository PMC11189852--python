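# renaldwi

Quantitative diffusion MRI of renal interstitial fibrosis, end to end on
synthetic data: forward simulation of multi-b and multi-TE-multi-b kidney
DWI on a digital phantom cohort, voxel-wise ADC / IVIM / DKI fitting,
D-T2 spectrum inversion with compartment fractions, corticomedullary
difference (CMD) biomarkers including a spectral CMD, and the cohort-level
diagnostic analysis (group tests, ROC with Youden cutoffs, multivariable
score models, CKD-EPI eGFR).

It is written for imaging scientists who want a tested, reproducible
reference implementation of this analysis chain — the original patient
data are not public, so the package ships a calibrated synthetic cohort
generator whose group structure mirrors the published statistics.

## Models

* **ADC** — two-point mono-exponential: ADC = ln(S_0/S_800) / (800·10⁻³),
  in μm²/ms.
* **IVIM** (segmented, b ≤ 800 s/mm², threshold 200):
  S(b)/S₀ = f·e^(−b·D*) + (1−f)·e^(−b·D); a weighted log-linear tail fit
  gives D and f, then D* is fitted with (D, f) frozen.
* **DKI** (200 ≤ b ≤ 2500): ln S = c₀ − b·MD + (1/6)·MK·MD²·b², a
  quadratic regression with free intercept.
* **DR-CSI** — discrete D-T2 mixture on a 30×30 log-spaced mesh
  (D ∈ [0.3, 30] μm²/ms, T2 ∈ [5, 200] ms):
  S_i = Σ_{j,k} f(D_j, T2_k)·e^(−b_i·D_j)·e^(−TE_i/T2_k), inverted by
  Tikhonov-regularized NNLS; compartments A (short T2), B (long T2),
  C (high D) give volume fractions V_A, V_B, V_C.
* **CMD** — cortical minus medullary ROI mean (Δ-prefixed); the spectral
  CMD ΔQ_X applies a compartment filter and index-ramp order weights to
  the difference of the normalized cortical and medullary spectra.

See `docs/methods.md` for assumptions, calibration and numerical choices.

## Worked example

```python
from renaldwi import DEFAULT_SEED, run_pipeline

frame, tables = run_pipeline(seed=DEFAULT_SEED)   # 42 subjects, ~2 min
print(tables["table3_group_comparison"]
      [["parameter", "mild_mean", "moderate_severe_mean", "p"]].head(3))
```

prints

```
       parameter  mild_mean  moderate_severe_mean         p
0   Cortical ADC   2.873246              2.423649  0.000011
1  Medullary ADC   1.825822              1.796029  0.495045
2          d ADC   1.047425              0.627619  0.000053
```

— cortical ADC separates mild from moderate-severe fibrosis (lower with
more fibrosis, Mann-Whitney p < 0.001), medullary ADC does not, and the
corticomedullary difference ΔADC shrinks toward zero in the fibrotic
group.  `frame` is the per-subject wide table (one row per subject:
cortical, medullary and Δ values of every parameter plus ΔQ_B and ΔQ_C);
`tables` also contains the per-marker ROC table and the multivariable
score models, where combining cortical V_B, ADC and f reaches AUC ≈ 0.98
on the default synthetic cohort.

The same pipeline is available as numbered analysis drivers
(`analysis/01_simulate_cohort.py` … `06_auc_consistency.py`, writing
their tables to `results/`) and as a CLI:

```bash
renaldwi all --config run.yaml      # simulate → fit → spectra → ROI → tables
```

where `run.yaml` must set an explicit `seed` (every run is byte-for-byte
reproducible).

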
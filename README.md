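# irllc — inversion-recovery lesion-to-liver contrast

`irllc` is a simulation and analysis toolkit for a question from
MR-guided liver ablation: **which inversion time (TI) maximizes the
visibility of a hepatic lesion against liver parenchyma in unenhanced
magnitude inversion-recovery (Look-Locker) imaging?**

During MR-guided thermoablation, gadolinium contrast is reserved for the
post-ablation check, so targeting has to work on unenhanced images. On a
standard T1-weighted spoiled-gradient-echo (VIBE) sequence, small
lesions can be nearly isointense to liver. Because malignant lesions
have markedly longer T1 (~1200 ms) than liver parenchyma (~650 ms at
1.5 T), an inversion-recovery readout with a well-chosen TI can strongly
amplify that difference — most of all near the TI that nulls the
parenchyma signal.

The package provides:

- **Signal models** — three-parameter magnitude IR signal
  `S(TI) = |A − B·exp(−TI/T1*)|`, the Look-Locker correction
  `T1 = T1*(B/A − 1)`, null-point arithmetic `TI_null = T1*·ln(B/A)`,
  and the spoiled-gradient-echo steady state used for the VIBE
  comparator.
- **Synthetic cohort generator** — a reproducible population of 44
  patients / 51 lesions with a fixed tumor-entity mix (20 colorectal
  metastases, 12 HCC, ...), lesion diameters 6–41 mm, and per-entity
  truncated-normal T1 distributions calibrated to the population means
  (lesions 1187 ± 456 ms, parenchyma 654 ± 96 ms, with HCC/CRC subgroup
  structure). Each lesion is rendered as a digital liver-slice phantom
  and imaged at the 8-point TI grid {148, 228, 548, 628, 946, 1025,
  1343, 1743} ms with Rician noise.
- **T1 mapping** — ROI-level and per-pixel three-parameter fits with
  exhaustive polarity restoration, verified against a brute-force grid
  oracle.
- **Contrast measurement** — deterministic "as large as possible" ROI
  placement avoiding necrosis and vessels, and the lesion-to-liver
  contrast statistic

  `LLC = |(SI_liver − SI_lesion)| / SI_liver`

- **Statistics** — Shapiro–Wilk screening, paired t / exact Wilcoxon
  signed-rank comparisons of each TI against VIBE, tie-corrected
  Friedman omnibus with Dunn–Bonferroni post hocs, and Kruskal–Wallis
  (exact by enumeration at small n) for group comparisons.
- **TI planning** — expected-LLC curves over a TI grid for arbitrary
  tissue pairs, noise-aware via Monte-Carlo, plus field-strength scaling
  of a recommended TI (≈ +30% at 3 T).

## Worked example

Simulate the default cohort at SNR 20 and summarize contrast per
condition:

```python
from irllc import AcquisitionSpec, CohortConfig, run_contrast_pipeline, run_paper_battery

table = run_contrast_pipeline(CohortConfig(seed=8), AcquisitionSpec(), seed=8)
print(table.groupby("condition")["llc"].agg(["mean", "std"]).round(2))
```

```
           mean   std
condition
TI148      0.53  0.32
TI228      1.73  1.61
TI548      0.52  0.28
TI628      0.64  0.21
TI946      0.55  0.26
TI1025     0.49  0.25
TI1343     0.36  0.20
TI1743     0.24  0.15
VIBE       0.39  0.17
```

Mean LLC peaks at TI 228 ms — just past the parenchyma null, where the
liver signal is suppressed but the long-T1 lesion still carries signal —
and decays monotonically at long TIs, where both tissues approach full
recovery. The paired comparison of the best TI against the VIBE
comparator:

```python
battery = run_paper_battery(table)
rep = [r for r in battery.reports if r.comparison == "all: TI228 vs VIBE"][0]
print(f"{rep.test}: {rep.comparison}  p = {rep.p_raw:.2e}")
# wilcoxon_signed_rank: all: TI228 vs VIBE  p = 5.30e-10
```

Forward planning for a given tissue pair from the command line:

```sh
$ irllc optimize --t1-liver 654 --t1-lesion 1187 --sigma 0.05 --seed 1
optimal TI: 318 ms (expected LLC 4.944); scaled by 1.3: 413 ms
```

The noise-aware optimum sits at the parenchyma null of the apparent
relaxation time (654/1.4 · ln 2 ≈ 324 ms); on the coarse clinical
8-point grid the best achievable conditions are the short TIs flanking
it. The full pipeline is also available as `irllc simulate`,
`irllc analyze`, `irllc fit`, `irllc stats` and `irllc report`; see
`irllc --help`.

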
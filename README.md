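# femcalc

Zone-wise quantification of common femoral artery (CFA) calcification from CT
angiography, with the downstream outcome analysis relating calcification
density to twelve-month primary patency after stenting of the CFA and its
bifurcation.

**Who it is for.** Vascular-imaging researchers who want a reproducible,
scriptable version of the zone-specific calcification workflow used in
femoral-bifurcation stenting studies: a tubular region of interest along
extracted centerlines, a patient-adaptive Hounsfield-unit (HU) detection
threshold, a three-zone partition of the bifurcation, per-zone plaque metrics,
and the statistics connecting them to restenosis. Because clinical CTA series
and follow-up tables are rarely shareable, the package also ships simulators —
a bifurcation phantom with voxel-exact ground truth and a limb-level cohort
generator — so every stage runs and is tested without any clinical data.

## The model in brief

- **ROI**: voxels within radius *r* (default 6 mm) of the CFA→DFA and CFA→SFA
  centerlines.
- **Adaptive threshold**: *T* = mean + *k*·SD of the HU values in a narrow
  (1.5 mm) tube hugging the centerline, default *k* = 2; operator override
  supported. Calcium = ROI voxels with HU ≥ *T*; lumen = ROI voxels in
  [150 HU, *T*).
- **Zones** (half-open arc intervals between landmarks P2–P6): Zone 1
  proximal CFA [P2, P3), Zone 2 distal CFA [P3, P4), Zone 3 bifurcation and
  ostia [P4, P5) ∪ [P4, P6), with P5/P6 two centimetres past the DFA/SFA
  ostia along the vessel.
- **Metrics per zone**: calcium volume (mm³), min/median/max density (HU over
  calcified voxels), calcium-to-lumen volume ratio (%).
- **Outcomes**: primary patency = PSVR ≤ 2.4 without target lesion
  revascularisation; Wilcoxon rank-sum comparisons with Benjamini–Hochberg
  FDR; logistic odds ratios; ROC with Youden-index threshold discovery
  (J = sensitivity + specificity − 1, DeLong AUC CI); bias-corrected bootstrap
  validation of the threshold; ICC(2,1) inter-observer agreement.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from femcalc.phantom import default_cohort_config, generate_cohort
from femcalc import stats

cohort = stats.add_patency(
    generate_cohort(default_cohort_config(n_limbs=84, seed=1, attrition=False))
)
ev = cohort[cohort["patency"].notna()]
roc = stats.roc_youden(ev["zone2_median_hu"], ev["patency"], positive="restenosis")
boot = stats.bootstrap_threshold(ev["zone2_median_hu"], ev["patency"], B=1000, seed=1)
fit = stats.fit_logistic(
    ev.assign(dense=(ev["zone2_median_hu"] >= roc.threshold).astype(int),
              y=(ev["patency"] == "restenosis").astype(int)),
    "y", ["dense"],
)
print(f"AUC = {roc.auc:.2f} ({roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f}), direction: {roc.direction}")
print(f"Youden threshold = {roc.threshold:.0f} HU "
      f"(sensitivity {roc.sensitivity:.0%}, specificity {roc.specificity:.0%})")
print(f"bootstrap (B=1000, BC): {boot.estimate:.0f} HU ({boot.ci_low:.0f}-{boot.ci_high:.0f})")
print(f"OR for density >= threshold: {fit.odds_ratio('dense'):.2f}")
```

prints

```
AUC = 0.75 (0.62-0.88), direction: less
Youden threshold = 1024 HU (sensitivity 71%, specificity 78%)
bootstrap (B=1000, BC): 1024 HU (904-1343)
OR for density >= threshold: 0.12
```

Reading this: on an 84-limb simulated cohort whose distal-CFA (Zone 2) median
calcification density is drawn from outcome-specific distributions (patent
median 1122 HU vs restenosis 858 HU), low density predicts restenosis
(`direction: less`), the discovered cut-off falls between the two group
medians, the bootstrap confirms its stability, and limbs at or above the
cut-off have roughly an 88% lower odds of restenosis — dense calcification is
protective in this model.

The same chain runs from the shell on a synthetic phantom plus cohort:

```sh
femcalc run --out out/ --seed 7
# pipeline done: detection threshold 339.1 HU, Youden 886 HU, AUC 0.85, patency 79.3%
```

which writes `phantom.nii.gz`, `segmentation.nii.gz`, `centerlines.csv`,
`landmarks.csv`, `zone_metrics.csv`, `cohort.csv`, `comparison_12m.csv`,
`roc_curve.csv`, `stats.json` and a seed/config-hash `manifest.json` under
`out/`. Individual stages are available as `femcalc phantom | cohort |
quantify | zones | stats`, all configured by one YAML file.

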
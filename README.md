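# glymphflow

Quantitative analysis of glymphatic drainage from brain MRI: perivascular
-space (PVS) and ventricle morphometry on axial T2 slices, pharmacokinetic
modelling of dynamic contrast-enhanced (DCE) MRI concentration–time curves
(CTCs), K-means typing of those curves into periarterial vs perivenous flow
patterns, and the group-comparison / ROC / correlation statistics that tie
the imaging markers to clinical sleep-apnea severity and cognition scores.

The package is aimed at neuroimaging researchers studying glymphatic
(CSF–interstitial fluid) clearance, in particular in obstructive sleep apnea
(OSA) cohorts with normal controls (NC) and a post-CPAP treatment arm.
Because clinical MRI/polysomnography data of this kind are rarely shareable,
the package ships a first-class synthetic-cohort generator with known ground
truth, so every stage of the analysis is testable end to end.

## The models at the core

**Morphometry.** Each structure is quantified as a relative area ratio on a
single axial slice, e.g. PVS area in the frontal cortex divided by the total
brain area at that level. Binarization uses Otsu's threshold (with manual
override), inversion makes the T2-bright fluid spaces the mask foreground,
and areas are pixel counts × pixel area.

**Extended (modified two-compartment) Tofts model.** The tissue concentration
driven by an arterial input function Cp(t) is

    Ct(t) = vp·Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^(−kep(t−τ)) dτ

with transfer constant Ktrans [1/min], efflux rate kep [1/min], EES fraction
ve = Ktrans/kep and plasma fraction vp. The convolution is evaluated exactly
for a piecewise-linear AIF; fitting is bounded multi-start nonlinear least
squares. Signal is converted to gadolinium concentration by inverting the
spoiled-gradient-echo steady-state signal equation.

**Curve typing.** From each ROI-mean CTC three semi-quantitative features
are extracted — peak concentration, wash-in rate (steepest ascending slope)
and wash-out rate (negated post-peak least-squares slope, mM/min). K-means
(k selected by the elbow method on the within-cluster sum of squares)
clusters the curves on (wash-in rate, peak concentration); the cluster with
the higher centroid peak is type I (periarterial: steep and high), the other
type II (perivenous: shallow and low).

**Statistics.** Two-sided Mann–Whitney U-tests (exact for small untied
samples), Pearson chi-square, ROC analysis with a Youden-index operating
point, pairwise-complete Spearman correlation matrices, and the clinical
severity cutoffs (AHI 5/30 events/h; lowest SaO₂ 80/90 %).

## Worked example

```python
import glymphflow as gf

report = gf.run_pipeline(seed=1, fit_tofts=False)
pre = report["typing_pre"]["summary"]["proportions"]
print(f"selected k = {report['typing_pre']['selected_k']}")
print(f"type-I proportion: NC = {pre['NC']['I']:.3f}, "
      f"OSA_pre = {pre['OSA_pre']['I']:.3f}")
roc = {r["score"]: r for r in report["stats"]["roc"]
       if r["task"] == "typeII_vs_typeI"}
print(f"peak AUROC (type II vs I) = {roc['peak_concentration']['auroc']:.3f}")
```

prints

```
selected k = 2
type-I proportion: NC = 0.293, OSA_pre = 0.426
peak AUROC (type II vs I) = 1.000
```

i.e. the elbow method finds the two flow-pattern clusters, the simulated OSA
group carries a larger share of type-I (periarterial) curves than the
controls, and peak concentration separates the two curve types almost
perfectly — the qualitative behaviour the analysis is designed to detect.

The same pipeline is available from the shell:

```bash
glymphflow run-all --seed 1 --out-dir out/
glymphflow simulate --seed 1 --out-dir cohort/
glymphflow features --ctcs cohort/ctcs.csv --out features.csv
glymphflow classify --features features.csv --subjects cohort/subjects.csv \
    --out typing.json
```

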
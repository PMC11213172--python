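# methylsieve

Bootstrap-scored CpG biomarker selection and classification for DNA
methylation arrays.

## The problem

Methylation arrays measure the methylated fraction (beta value) at
hundreds of thousands of CpG sites.  Finding the handful of sites whose
methylation separates cases from controls — a usable diagnostic
signature — is hard when cohorts are small: single F-tests over ~10⁶
probes drown in multiple testing, and probes that pass a significance
gate are not necessarily the ones a classifier can use.

`methylsieve` implements a selection scheme that couples statistical
evidence with predictive value.  Over many stratified train/test splits
of the cohort, every probe is F-tested on the training samples and
BH-corrected; probes with q < 0.001 become that split's candidate set, a
classifier (radial SVM or maximum-likelihood LDA) is fitted on the
candidates, and each candidate receives the score

```
Score = F1,weighted · (−log10 p_uncorrected)
```

where F1,weighted is the model's support-weighted one-vs-rest F1 on the
held-out samples.  Scores are averaged over all usable splits (a probe
scores 0 in splits where it misses the gate).  The averaged scores form
a multi-modal distribution; Otsu's threshold extracts the upper mode(s),
and a Hartigan dip test decides whether the extracted scores are still
multi-modal — if so, the whole bootstrap reruns on the extracted subset
until the dip test accepts unimodality.  Finally, collinear probes
(pairwise variance-inflation factor 1/(1−r²) > 5) are pruned, keeping
the higher-scoring member of each pair.

Because real cohorts rarely come with ground truth, the package ships a
fully specified synthetic validation: 25 control and 25 positive
samples over 10⁶ uniform-noise probes, with 30 planted differential
probes in three discriminability tiers (high: mean difference 25–40
percent points at SD 6–8; medium: 15–30 at 8–10; low: 10–20 at 10–12).
A biomarker-assumption prefilter, the selection loop, and a tier-wise
detection report complete an end-to-end test with known answers.

The package also provides the surrounding toolkit: beta/percent →
M-value transform, SNP/sex-chromosome/detection filtering from an
annotation table, parametric ComBat batch correction, bootstrap
performance summaries (median weighted one-vs-rest F1), a
variance-stress sensitivity analysis (uniform samples on
[μ − A·σ, μ + A·σ] for A = 1..10), and held-out-group PCA projection.

## Worked example

Run the synthetic validation end to end (10⁵ background probes, 500
bootstrap iterations, binary radial-SVM selection):

```python
import methylsieve as ms

config = ms.ValidationWorkflowConfig(
    synthetic=ms.SyntheticConfig(n_background=100_000),
    selection=ms.SelectionConfig(n_iterations=500, comparison="binary",
                                 model=ms.ClassifierSpec("svm_rbf")),
    seed=0)
result = ms.run_validation_workflow(config)

report = result.detection
print(f"prefilter retained : {result.n_prefiltered} probes")
r = result.selection.rounds[0]
print(f"round 1            : Otsu threshold {r.otsu_threshold:.2f}, "
      f"dip {r.dip_statistic:.3f} (p = {r.dip_pvalue:.2f})")
print(f"selected (pre-VIF) : {len(result.selection.final_probes_pre_vif)} probes")
for tier in ("high", "medium", "low"):
    print(f"{tier:>6}: {report.n_detected[tier]} / {report.n_planted[tier]} detected")
print(f"false positives    : {report.n_false_positive}")
```

Output:

```
prefilter retained : 22102 probes
round 1            : Otsu threshold 5.27, dip 0.062 (p = 0.94)
selected (pre-VIF) : 15 probes
  high: 5 / 5 detected
medium: 9 / 10 detected
   low: 1 / 15 detected
false positives    : 0
```

Reading this: the biomarker prefilter keeps ~22k of 100k probes (mostly
noise probes whose observed group mean difference exceeded 10 percent
points by chance — they anchor the zero mode of the score
distribution).  After 500 bootstrap splits, Otsu's threshold at 5.27
separates the scored signal probes from that zero mode; the dip test
sees no residual multimodality (p = 0.94), so selection stops after one
round with 15 probes: all 5 high-discriminability probes, 9 of 10
medium, 1 of 15 low — and not a single background probe.  Planted
probes the model cannot distinguish from noise (most of the low tier)
are the expected misses.

The same run is available from the shell:

```bash
methylsieve validate --background 100000 --iterations 500 --seed 0 --out runs/demo
```

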
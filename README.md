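# tzpheno

Quantitative phenotyping of ciliary **transition-zone (TZ)** fluorescence
and cilia-dependent behaviour in *C. elegans*.

The TZ is the ~0.2–1 µm gating compartment at the ciliary base. Grading
how a missense variant of a TZ protein (e.g. an MKS-module component such
as MKSR-2/B9D2) disrupts the compartment requires a battery of image and
behaviour metrics, each with precise measurement conventions:

- **Signal length** — full width at half maximum (FWHM) of a line-scan
  profile: the distance between the outermost half-max crossings flanking
  the peak, `level = baseline + (max − baseline)/2`.
- **Net TZ intensity** — integrated intensity in a 40×40 px box around
  the TZ pair, background-corrected from the 164-pixel ring left by
  enlarging the box one pixel per side (42×42); exactly unbiased under
  constant and linear backgrounds. Values are normalised to the
  wild-type mean.
- **Allele-competition index** — heterozygote fluorescence of a tagged
  allele as a percentage of the tagged homozygote,
  `100 × mean(het)/mean(homo)`. Under equal recruitment of both alleles
  the expectation is 50%; the tagged homozygote is 100% by construction.
- **3D compartment metrics** — compartment volume by half-max
  thresholding of z-stacks resampled to a 0.1 µm step, axial peak counts
  (prominence ≥ 20% of range), and a hollow-core ratio (core vs shell
  intensity in the central plane; < 1 means the signal is excluded from
  the TZ axis).
- **Behavioural scores** — dye-filling frequencies over 0–4 filled
  phasmid neurons, roaming indices normalised to wild type, and osmotic
  avoidance retention curves right-censored at 10 min.
- **Statistics** — Shapiro–Wilk normality gate dispatching to one-way
  ANOVA + Tukey HSD or Kruskal–Wallis + Dunn (Bonferroni), α = 0.05.

No public micrographs exist for these conventions, so the package ships
a first-class **synthetic-data generator**: phasmid-cilium scenes
(hollow-shell TZ with axial periodicity and optional proximal decay,
pan-ciliary marker, Gaussian PSF, Poisson + read noise) and behavioural
cohorts with known ground truth. Every estimator is validated by
parameter recovery against that truth; see `docs/methods.md`.

## Worked example

Simulate wild-type-like and disrupted-variant-like wide-field cohorts
(10 scenes each), measure them, and compare groups:

```python
from tzpheno import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "mode": "simulate", "seed": 7, "outdir": "out",
    "metrics": ["fwhm_length_um", "net_intensity", "asymmetry_index"],
    "genotypes": [
        {"name": "WT", "preset": "widefield_wt", "n_scenes": 10},
        {"name": "G155S", "preset": "widefield_g155s", "n_scenes": 10},
    ],
})
summary = run_pipeline(cfg)
```

Output (group means; adjusted p from the gated comparison):

```
fwhm_length_um   WT 0.795 µm   G155S 0.717 µm   p_adj = 1e-08   (anova_tukey)
net_intensity    WT 48078      G155S 8783       p_adj < 1e-12   (anova_tukey)
asymmetry_index  WT 0.493      G155S 0.582      p_adj = 5.7e-06 (anova_tukey)
```

The disrupted variant shows the expected signature: a shorter TZ signal
(0.72 vs 0.80 µm — the wild-type value is the true 0.8 µm length plus
sub-pixel PSF broadening), ~4-fold lower net intensity, and proximal
enrichment (asymmetry index > 0.5, where 0.5 is symmetric). The same
stages are scriptable from the shell:

```bash
tzpheno simulate scene --config scene.yaml --seed 1 --out scenes/s1/
tzpheno quantify tz --images imgs/ --annotations ann.json --out tz.csv
tzpheno compare --table tz.csv --metric net_intensity --out stats.json
tzpheno simulate cohort --config assay.yaml --out cohort.csv
tzpheno score --cohort cohort.csv --assay osmotic --reference WT --out scores.csv
tzpheno run --config run.yaml
```

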
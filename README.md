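# mitovar

Quantifying intra-individual variability of mitochondrial markers in
skeletal muscle, with a synthetic single-fibre cohort generator, two
per-fibre OXPHOS-deficiency classifiers, agreement benchmarking, and
resampling-based variability thresholds for biopsy-level measures.

## Scientific problem

In mitochondrial myopathy (e.g. carriers of the m.3243A>G mutation),
oxidative phosphorylation (OXPHOS) deficiency is mosaic: individual muscle
fibres range from normal to severely deficient, and the *proportion* of
deficient fibres in a biopsy section is a key clinical readout. So are two
homogenate measures: mitochondrial DNA copy number per nucleus (mtDNAcn)
and m.3243A>G heteroplasmy. All three are routinely compared across
biopsies, muscles and patients — but any such comparison is only meaningful
if it exceeds the variability expected between two samples of the *same*
tissue. This package estimates that intra-individual variability by
simulation and resampling, and derives percentile thresholds above which a
difference between two biopsies is unlikely to be sampling noise.

Two per-fibre classifiers are implemented and benchmarked against known
ground truth:

1. **Frequentist prediction-interval classifier.** Per-fibre OXPHOS marker
   intensity (NDUFB8 for complex I, MT-CO1 for complex IV) is regressed on
   the mitochondrial-mass marker VDAC1 in control fibres by ordinary least
   squares. A fibre is scored against the t-based 95% prediction band

   ŷ(x) ± t₍₀.₉₇₅, n−2₎ · s · √(1 + 1/n + (x − x̄)²/Sxx)

   over 10,000 bootstrap resamples of the controls; each model labels the
   fibre −1 (below band), 0 (inside) or +1 (above), and the mean label is a
   certainty score in [−1, +1]. A fibre is called deficient when the mean
   label is ≤ −0.95, overabundant when ≥ +0.95.

2. **2D-mitoplot polygon consensus.** Investigators draw polygons on the
   (VDAC1, OXPHOS) plane delimiting deficient and overabundant regions;
   point-in-polygon membership labels each fibre per investigator, and an
   investigator-bootstrap yields a consensus certainty score with the same
   ±0.95 call rule.

Classifier output feeds a benchmarking stage (Cohen's and Fleiss' kappa
against ground truth, false-positive/false-negative rates, PPV, F1, with
fibre-count-weighted bootstrap confidence intervals) and a variability
engine that bootstraps per-section deficient proportions, enumerates
section pairs by anatomical relationship (same biopsy, same muscle,
longitudinally split biopsy, different muscle) and reports the distribution
of absolute differences per pairing strategy. The 97.5th percentile of each
distribution is the reported "difference threshold". mtDNAcn is estimated
by a staged bootstrap over qPCR standard curves (MT-ND1 copies divided by
half the diploid B2M copies), and heteroplasmy from pyrosequencing
triplicates with a pooled-SD replication diagnostic.

Because real single-fibre data of this kind is scarce, the package includes
a hierarchical synthetic-cohort generator (patients → muscles → biopsies →
sections → fibres) with controllable spatial drift of the deficient
proportion, per-section staining batch effects, investigator annotation
jitter, qPCR Cq noise and pyrosequencing replicate noise, so every
downstream method can be validated against known ground truth.

## Worked example

```python
import numpy as np
from mitovar import (
    CohortDesign, generate_cohort, generate_annotations,
    classify_frequentist, classify_by_polygons, consensus_certainty,
    benchmark_sections, bootstrap_section_proportions,
    enumerate_pairs, sample_abs_differences, summarize_distribution,
)

# one patient, two muscles, two biopsies each, three sections per biopsy
design = CohortDesign(n_patients=1, biopsies_per_muscle=2,
                      fibres_per_section=300, seed=42)
cohort = generate_cohort(design)
print(f"{len(cohort.fibres)} fibres in {len(cohort.sections)} sections")

# frequentist bootstrapped prediction-interval classification
calls = classify_frequentist(cohort.fibres, cohort.controls, "NDUFB8",
                             n_models=1000, seed=1)
n_def = (calls["final_call"] == "deficient").sum()
print(f"frequentist: {n_def}/{len(calls)} fibres called NDUFB8-deficient")

# 2D-mitoplot consensus from three simulated investigators
annotations = generate_annotations(cohort, n_investigators=3,
                                   boundary_jitter_sd=15.0, seed=2)
tables = [classify_by_polygons(cohort.fibres,
                               [a for a in annotations if a.investigator == inv],
                               "NDUFB8")
          for inv in ("I1", "I2", "I3")]
consensus = consensus_certainty(tables, n_resamples=10_000, seed=3)
n_def = (consensus["final_call"] == "deficient").sum()
print(f"mitoplot consensus: {n_def}/{len(consensus)} fibres called deficient")

# benchmark against ground truth, per section
bench = benchmark_sections(consensus, cohort.fibres, "NDUFB8",
                           restrict_to_ground_truth=False)
print(f"per-section kappa: {bench['kappa'].min():.3f} to {bench['kappa'].max():.3f}")

# intra-biopsy versus inter-muscle variability of the deficient proportion
deficient = (consensus["final_call"] == "deficient").to_numpy()
sections = cohort.fibres["section"].to_numpy()
dists = {s: bootstrap_section_proportions(deficient[sections == s],
                                          section=s, seed=4).draws
         for s in cohort.sections["section"]}
for strategy in ("intra_biopsy", "inter_muscle"):
    pairs = enumerate_pairs(cohort.sections, strategy)
    diff = sample_abs_differences(dists, pairs, n_iterations=100_000, seed=5)
    s = summarize_distribution(diff)
    print(f"{strategy}: median |difference| = {100 * s.median:.1f} "
          f"points, 97.5th percentile = {100 * s.p97_5:.1f} points")
```

Output:

```text
3600 fibres in 12 sections
frequentist: 1800/3600 fibres called NDUFB8-deficient
mitoplot consensus: 1226/3600 fibres called deficient
per-section kappa: 0.992 to 1.000
intra_biopsy: median |difference| = 2.7 points, 97.5th percentile = 8.7 points
inter_muscle: median |difference| = 7.3 points, 97.5th percentile = 16.0 points
```

The run reproduces the qualitative findings the package is built around:
the frequentist classifier over-calls deficiency when per-section staining
batch effects are present (1,800 calls against roughly 1,200 truly
deficient fibres), while the human-in-the-loop polygon consensus stays
close to ground truth (κ ≥ 0.99); and the deficient proportion varies
substantially more between muscles than between sections of one biopsy, so
comparisons need anatomy-specific difference thresholds.

## Command-line interface

Every stage is also exposed through the `mitovar` CLI:

```bash
mitovar simulate --seed 1 --out run/              # synthetic cohort + assays
mitovar classify --fibres run/fibres.csv --controls run/controls.csv \
    --protein NDUFB8 --out run/calls.csv          # frequentist classifier
mitovar consensus --fibres run/fibres.csv --annotations run/annotations.json \
    --protein NDUFB8 --out run/consensus.csv      # polygon consensus
mitovar benchmark --fibres run/fibres.csv --calls run/calls.csv \
    --protein NDUFB8 --out run/benchmark.csv      # agreement vs ground truth
mitovar variability --fibres run/fibres.csv --calls run/consensus.csv \
    --strategy intra_biopsy --strategy inter_muscle --out run/var.csv
mitovar mtdnacn --plate run/qpcr_plate.csv --out run/mcn.csv
mitovar heteroplasmy --pyroseq run/pyroseq.csv --out run/het.csv
mitovar run-all --seed 1 --out run/               # full pipeline + report.json
```

All tables carry a `# mitovar-schema: <name>/<version>` header and readers
reject unknown schemas.

## Reproduction

The headline quantities of a full pipeline run (benchmark statistics per
classifier, variability medians and 97.5th-percentile thresholds per
pairing strategy, mtDNAcn and heteroplasmy summaries) can be regenerated
deterministically with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This runs the complete simulate → classify → benchmark → variability →
thresholds pipeline at desk scale (a few seconds on one CPU) and writes a
JSON mapping of quantity names to `{"value", "n"}` pairs. All randomness
derives from `--seed` through per-stage seeds, so repeated runs with the
same seed are byte-identical. See `docs/methods.md` for the statistical
model, generator assumptions and numerical choices.
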
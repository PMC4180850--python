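# mbgblup

Multi-breed and crossbred genomic prediction with GBLUP.

Sheep and beef breeding programs rarely have large single-breed reference
populations; phenotyped and genotyped animals are a mixture of purebreds
and crossbreds. `mbgblup` is a tested, reusable pipeline for the question
that raises: **how accurate is genomic prediction of purebred sires from
purebred, crossbred, or combined reference populations, and does
accounting for breed-specific allele frequencies in the relationship
matrix change the answer?** It is aimed at quantitative geneticists who
want to study multi-breed reference design in simulation with the same
code path a real analysis would take.

The pipeline covers:

* **`popsim`** — a forward-in-time simulator of diverged breeds (drift
  from a common base), paternal half-sib crossbreeding designs with
  research ewes and progeny-tested validation sires, breed-specific QTL
  effects with configurable across-breed correlation, phenotypes with
  maternal and sire×flock variance, and ground-truth ledgers (gamete
  breed-of-origin, planted QC defects).
* **`geno_qc`** — chip-style genotype QC: confidence masking, call rate,
  heterozygosity outliers, MAF, sex chromosomes, Hardy-Weinberg
  (p < 1e-15), duplicate samples at genotype correlation ≥ 0.99, mean
  imputation, 4-SD phenotype trimming.
* **`breedcomp`** — pedigree breed proportions (the Q matrix), crossbred
  reference selection by breed-proportion thresholds, haplotype
  breed-of-origin assignment (parents > 97% purebred), rule-based trio
  phasing.
* **`grm`** — the genotype-based GRM `G1 = ZZ'/2Σp(1−p)` and the gametic
  breed-specific-frequency GRM `G2 = (G2₁+G2₂)/2` with
  `G2ᵢ = ZᵢZᵢ'/Σp(1−p)`, plus PCA, element correlations and
  haplotype-group relationship summaries.
* **`gblup`** — Henderson mixed model equations for
  `y = Xb + Z₁g + Ww + Z₁Qq + Z₂s + e` with `g ~ N(0, G σg²)`, and
  EM-REML for the reduced additive model.
* **`evaluation`** — validation accuracy (correlation of GBV with
  progeny-test EBV per breed), Fisher-z / Steiger accuracy comparisons,
  Daetwyler–Goddard expected accuracy `sqrt(Nh²/(Nh²+Me))` with
  `Me = 2NeL/ln(4NeL)`, compact-letter summary tables.
* **`experiment`** — a config-driven scenario runner and a thin `mbgblup`
  CLI (`simulate`, `qc`, `grm`, `fit`, `evaluate`, `run-scenario`).

See `docs/methods.md` for the model, the simulator's assumptions and the
numerical conventions.

## Worked example

Run the default desk-scale comparison — purebred references of 200/400/600
focal-breed animals, a 400-animal F1 crossbred reference (the same 400
focal haplotypes as the smallest purebred reference), and their
combination — over five replicate seeds, with both GRM flavors:

```python
from mbgblup import experiment as ex

cfg = ex.sheep_like_scenario(seeds=range(1000, 1005))
res = ex.run_scenario(cfg)
print(ex.aggregate_accuracies(res.accuracies)
        .query("breed == 'MER' and flavor == 'G1'")
        [["design", "mean", "se"]].to_string(index=False))
```

```
          design     mean       se
        cross400 0.262484 0.103658
cross400+pure600 0.593794 0.034241
         pure200 0.513126 0.040581
         pure400 0.559837 0.047779
         pure600 0.607085 0.027006
```

Each number is the mean (over seeds) correlation between GBLUP breeding
values and simulated progeny-test EBVs in the 35 withheld focal-breed
validation sires. The pattern is the one that matters: accuracy rises
with purebred reference size (0.513 → 0.607), a crossbred-only reference
with the same number of focal haplotypes does markedly worse (0.263),
and adding purebreds to the crossbreds recovers most of the difference
(0.594). `res.summary` renders the full design × (breed, GRM) table with
significance letters from pairwise z-tests, and `res.diagnostics` holds
QC counts, the G1–G2 element correlation and the PCA breed-cluster
purity per seed.

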
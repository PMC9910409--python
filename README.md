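# diploidizer

Analyses of post-whole-genome-duplication **diploidization** in allopolyploid
genomes: how an allopolyploid — a hybrid carrying two diverged parental
subgenomes (D and S) — gradually loses duplicated genes, whether that loss is
biased toward one subgenome, whether the surviving "missing gene" loci are
degraded pseudogene remnants, whether one subgenome dominates expression, and
how transposable-element (TE) activity has unfolded since the polyploidy
event.  It is written for comparative genomicists working with a polyploid
assembly plus its diploid progenitor genomes (the motivating system is an
allotetraploid grass with *distachyon*-like BhD and *stacei*-like BhS
subgenomes).

The package consumes standard upstream artifacts (FASTA, GFF3, an
OrthoFinder/GENESPACE-style orthogroup table, a defragmented RepeatMasker TE
table, paired intact-LTR FASTA, HTSeq-style count tables) — it does not do
orthology inference, repeat discovery, or read mapping itself.

## What it computes

* **Orthogroup census** — classify each orthogroup as complete,
  single-missing (exactly one genome unit lacks a member: the gene-loss
  signal), or multi-missing; 2×2 Pearson chi-square with Yates continuity
  correction for differential loss between genomes and for D-vs-S biased
  loss against the subgenome gene totals.
* **Synteny-walk pseudogene locator** — from the diploid ortholog of a
  missing gene, walk outward along the diploid chromosome collecting 5
  informative (single-ortholog) neighbors per side, skipping genes with
  zero or multiple orthologs; discard after >25 genes examined on a side or at the chromosome
  end; require a joint 200-kb window on one polyploid chromosome containing
  ≥4 ortholog positions from each side; the region between the closest
  in-window anchors is the candidate locus, discarded if >20 kb.
* **Pseudogene characterization** — a codon- and intron-aware local
  protein-to-genome alignment of the diploid peptide into the candidate
  region, then: alignment-length deficit (3·|peptide| − aligned bp),
  premature termination codons (in-frame stops before the final aligned
  codon), pairwise dN/dS by Nei–Gojobori (1986) counting with Jukes–Cantor
  correction (ω invalid when dS = 0 or saturated), expression (TPM per
  tissue; non-expression as TPM = 0), and TE containment.  A resampling
  control re-runs the same procedure on conserved genes (by default 1,000
  trials of 224 D + 240 S genes) and yields (r+1)/(n+1) empirical p-values,
  plus one-sided exact binomial tests for non-expression enrichment.
* **Expression bias** — TPM (per-tissue 10⁶ normalization); homeolog
  expression bias per tissue (filter pairs with both TPM < 1, drop ties,
  two-sided exact binomial vs 0.5 at Bonferroni α = 0.0125); subgenome
  dominance on raw counts against the transcriptome-length null.
* **TE analysis** — per-class composition and Gypsy:Copia ratios;
  subgenome-specific families (≥5 copies, ≥90% on one subgenome, inclusive
  boundaries) with per-chromosome percentages and a paired t-test;
  gene–TE overlap (same-strand) and distances; intact-LTR insertion dating
  T = D/(2t) with Kimura 2-parameter D and t = 1.3×10⁻⁸ subs/site/year,
  family lifespans and young-element fractions.
* **Synthetic data** — a generator that emulates the whole scenario (two
  diverged progenitors, one allopolyploid, an outgroup, planted pseudogene
  lesions, TE families of known specificity, LTR pairs of known age,
  counts with controlled homeolog bias) and writes a truth table, so every
  stage is testable without downloads.  Same seed ⇒ byte-identical files.

## Worked example

```
diploidizer simulate --out ds --seed 1
diploidizer run-all --config ds/config.yaml --out results --seed 1
```

or in Python:

```python
from diploidizer.synthetic_data import SimulationConfig, generate_dataset
from diploidizer.pipeline import Pipeline

paths, truth = generate_dataset(SimulationConfig(seed=1), "ds")
pipe = Pipeline(paths["config"], seed=1)
print(pipe.run_census())
print(pipe.run_locate())
summary = pipe.run_characterize(n_trials=1000)
print(summary["pseudogenes"])
print(summary["control_mean"])
```

Output on this dataset (seed 1):

```
{'n_orthogroups': 350, 'categories': {'complete': 259, 'single_missing:Os': 35,
 'single_missing:BhS': 28, 'single_missing:BhD': 28}}
{'n_single_missing': 56, 'funnel': {'located': 56}}
{'n': 56, 'mean_length_deficit': 80.82, 'pct_ptc': 42.86, 'mean_omega': 0.5055,
 'n_omega_valid': 54, 'median_tpm': 0.0, 'pct_te_contained': 3.57}
{'mean_length_deficit': 0.041, 'ptc_fraction': 0.0, 'mean_omega': 0.1921,
 'median_tpm': 848.4, 'te_contained_fraction': 0.179, ...}
```

Reading: all 56 planted losses are single-missing and located; the remnant
cohort is truncated (mean 81 bp shorter than the diploid ortholog), 43%
carry a premature stop, and its mean ω ≈ 0.51 recovers the planted relaxed
ω = 0.5, against ω ≈ 0.19 (planted 0.2) and a 0.0% premature-stop rate in
the conserved control — the empirical p for each contrast is 1/1001.
(Floats rounded here; `report.json` holds full precision.)

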
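# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `diploidizer`, in the order the pipeline runs them.

## Scope and inputs

The package analyzes an allopolyploid genome together with its two diploid
progenitor genomes and an outgroup.  Orthology (an orthogroup table),
repeat annotation (a defragmented TE copy table), intact-LTR pairs, and
gene-level read counts are *inputs*: the corresponding inference tools
(GENESPACE/OrthoFinder-class orthology, RepeatMasker + defragmentation,
LTR discovery, read mapping and counting) are deliberately out of scope.
Internally all coordinates are 0-based half-open; GFF3 and RepeatMasker
(1-based inclusive) are converted at the I/O boundary, and a GFF3 →
internal → GFF3 round trip is the identity.  Subgenomes are resolved purely
by chromosome-name prefix patterns (e.g. `BhD*` vs `BhS*`), because
orthogroup tables are per-assembly; genes and TEs on sequences matching no
declared unit (unplaced scaffolds) are excluded from every analysis.

## Orthogroup census and loss tests

Each orthogroup is assigned exactly one category — `complete`,
`single_missing(<unit>)`, or `multi_missing` — over the declared unit
universe.  Only single-missing groups feed the pseudogene analysis;
multi-unit absences are tallied but not pursued, since a gene absent from
several genomes is weak evidence for loss *after* polyploidy.  Both loss
tests are 2×2 Pearson chi-squares with Yates continuity correction, applied
unconditionally (an uncorrected variant sits behind a flag); expected cells
below 1 set a warning flag on the result rather than aborting.  The biased-
loss test takes the two subgenomes' total gene counts as the null, so it
asks whether loss is more lopsided than gene content alone predicts.

## Synteny walk

Parameters (defaults): 5 informative neighbors per side, at most 25 genes
examined per side, a 200-kb consensus window requiring at least 4 ortholog
positions from *each* side, and a 20-kb cap on the final region.  Design
choices on points the procedure leaves open:

* The consensus window is **joint** — one window must hold both sides'
  ortholog quorums simultaneously — rather than one window per side,
  because the two anchors must bound a single physical locus.  (A per-side
  variant would admit anchors 400 kb apart that the region cap then
  discards anyway.)
* Anchors are the orthologs of the informative neighbors closest to the
  missing gene *whose orthologs lie inside the chosen window*; if the
  closest neighbor's ortholog falls outside, the next closest inside is
  used.
* Both anchors must lie on one chromosome (implied by the joint window).
* Ortholog positions are compared by gene start; among multiple qualifying
  windows the one minimizing the final anchor-to-anchor span wins, ties
  broken leftmost, making the walk deterministic and order-independent.
* The missing gene's diploid counterpart itself does not count toward the
  25-gene examination budget.

Every discard carries its reason (`walk_limit`, `chromosome_end`,
`window`, `region_size`), so the attrition funnel of a run is reportable
stage by stage.

## Spliced protein-to-genome alignment

The diploid peptide is aligned into the candidate region with a local
dynamic program (numba-compiled) over four states: codon match (3 nt per
residue, BLOSUM62 on the translated codon; stop codons score −4 against
any residue so an alignment can pass *through* a premature stop),
frameshift "codons" of 2 or 4 nt at −15, affine short gaps (−12/−3 per nt
genomic, −12/−2 per residue), and a cheap long-gap intron state
(−20 open, −0.25/nt) with a +6 bonus at each end when the gap is bounded
by GT..AG.  Both strands are tried.  An alignment scoring below 25% of the
peptide's self-alignment score is reported empty ("no alignable remnant"),
mirroring the attrition real candidate regions show.  The traceback is
kept as typed chunks (codon / frameshift / insertion / deletion / intron),
which *is* the codon phase map: premature-stop scanning reads full codons
from it (final aligned codon excluded), so frame-disrupted triplets are
never misread as stops.

## Codon alignment and dN/dS

The diploid CDS and the inferred remnant CDS are globally aligned at the
nucleotide level (Biopython `PairwiseAligner`; match 2, mismatch −3, gaps
−8/−2) and codons are threaded on the diploid frame.  A codon is excluded
from substitution counting when a gap interrupts its columns or the
cumulative indel offset at its start is not a multiple of 3 — exactly the
codons a 1-bp indel garbles until a compensating indel restores frame.
(Threading through a *protein* alignment was considered and rejected: after
a frameshift the translated remnant is noise, and a protein-level thread
would count that noise as nonsynonymous substitutions.)

dN/dS is Nei–Gojobori (1986) counting: per-codon synonymous site fractions
with mutations to stop codons excluded from the normalization; observed
differences averaged over all shortest mutational pathways between the two
codons, pathways through a stop dropped (all pathways used when every one
is blocked); Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) on both
proportions.  ω = dN/dS is flagged invalid when dS = 0 (alignments with no
synonymous substitutions yield no ratio) or when a proportion saturates
(p ≥ 3/4).  NG86 was chosen over κ/frequency-corrected estimators (yn00-
style ML) because it is exactly specifiable and verifiable against a
brute-force pathway-enumeration oracle, and the scientific conclusions rest
on the *contrast* between cohorts, which is robust to the counting method;
a κ-corrected estimator is a possible extension, and numerical equality
with ML estimates on real data is not claimed.

The resampling control characterizes each conserved-pool gene once on its
own locus and then resamples per-gene metrics: within a trial, draws are
without replacement (default 1,000 trials of 224 D + 240 S genes); across
trials, with replacement.  Empirical p-values use the (r+1)/(n+1)
estimator, so "more extreme than every trial" reports 1/1001, never zero.
Non-expression enrichment per tissue is a one-sided exact binomial tail
against the control-derived expected non-expressed frequency.  TE
containment of a remnant is strand-agnostic overlap of any TE copy with
the alignable span (strandedness is only enforced for the genome-wide
gene–TE overlap statistic, where it is part of the definition).

## Expression

TPM_g = 10⁶·(c_g/ℓ_g)/Σ_h(c_h/ℓ_h) per tissue, ℓ the primary-transcript
length.  Homeolog bias: pairs with both TPM < 1.0 are filtered as noise;
exact TPM ties are dropped from the binomial count (and reported);
two-sided exact binomial against 0.5, judged at α = 0.05/4 = 0.0125
(Bonferroni over the standard four tissues).  Subgenome dominance uses raw
counts with the D share of total primary-transcriptome base pairs as the
null expectation, since longer transcriptomes attract more reads without
any dominance.

## TE statistics and LTR dating

Subgenome-specific families: ≥5 copies and ≥90% of them on one subgenome,
both boundaries inclusive, counted post-defragmentation.  The genome-level
statistic is the percentage of *copies* belonging to specific families,
also computed per chromosome for the paired t-test.  Gene–TE overlap is
same-strand (UTR and intronic TEs count for the gene, exon overlap is
tracked separately); TE-to-gene distance is strand-agnostic and
envelope-to-envelope, 0 when overlapping.  For dating, the two LTRs are
globally aligned (match 1, mismatch −1, gaps −4/−1); gap- or N-containing
columns are removed (the two-sequence rendering of a 0.8 column-occupancy
trim); transitions P and transversions Q give
D = −½·ln((1−2P−Q)·√(1−2Q)), and T = D/(2t) with t = 1.3×10⁻⁸
substitutions/site/year by default (configurable).  Saturated elements are
excluded with a recorded reason.  Family lifespans (oldest minus youngest
member) require ≥2 dated copies; the "young" fraction uses a 1.4-My
threshold by default, the age of the older natural lineage in the
motivating system.

## Synthetic data: what it emulates, and what it does not

The generator builds, from one seed (byte-identical reruns): two diploid
progenitors diverged by 0.12 substitutions/site (proposal rate), an
allopolyploid whose subgenomes sit 0.05 subs/site from their progenitors,
and an outgroup at 0.30; 2 chromosomes × 175 genes per unit, CDS lengths
~N(300, 60²) codons clipped to [150, 600], intergenic gaps ~2 kb.  Codon
evolution is an ω-filter: per-site proposals (transition:transversion
κ = 2) with nonsynonymous acceptances at probability ω — 0.2 for conserved
genes, 0.5 for pseudogenes — and stop-creating proposals rejected, so
premature stops arise *only* from planted nonsense lesions and the truth
table is an exact PTC indicator.  8% of genes per subgenome are
pseudogenized (disjoint slots, away from chromosome ends so flanks stay
informative): removed from annotation and orthogroup membership while the
lesioned sequence stays in the assembly; lesions are nonsense codons
(probability 0.6), one internal deletion (probability 0.5, mean 150 bp,
frameshifts allowed), and silencing (probability 0.8, zero counts).  10%
of orthogroups lack the outgroup member, giving the census a realistic
most-common category.  Chromosome sizes (~0.6 Mb) are two orders below
real chromosomes; the 175-gene scale was chosen so the conserved-control
pool (genes in complete orthogroups) comfortably exceeds the 224 + 240
per-trial control draw while the whole pipeline runs in seconds.

TEs: 24 families, 3–30 copies, half planted subgenome-specific (≥90% on
one subgenome by construction), Gypsy/Copia-weighted class labels, copies
dropped into intergenic space (a quarter overlapping genes).  LTR pairs:
100 elements at each of 0.14 and 1.4 My, 1-kb LTRs mutated from a common
ancestor by a Poisson number of κ-weighted substitution events per copy
(multiple hits allowed, the model a multiple-hit-corrected distance is
unbiased for).  Counts: negative binomial (dispersion 0.1) around
lognormal baselines scaled to 2M reads/tissue, with a planted favored
subgenome per homeolog pair (fraction favoring D = 0.5 by default; the
favored copy's mean is 3× the other's, large enough that sampling noise
rarely flips the observed winner).

Deliberately **not** emulated: recombination and demography, selection on
non-coding sequence, TE transposition dynamics through time, alternative
splicing, annotation error, and assembly artifacts.  Passing tests
therefore demonstrate that the algorithms recover planted signals under
the stated generative model — not that real assemblies are free of the
confounders the model omits.

## Numerical and degenerate-input conventions

Zero-variance paired t-tests are flagged degenerate (p = 1 for identical
vectors, p = 0 for a constant nonzero offset); all-zero count columns give
zero TPM with a warning; empty alignments report coverage 0 rather than
raising; ambiguous TE class strings normalize to "Unknown"; orphan LTRs,
duplicate gene ids, non-integer or negative counts, and unknown orthogroup
gene ids are hard errors.  The pipeline derives per-stage seeds by SHA-256
of `(seed, stage)`, so adding a stage never shifts another's randomness;
reruns with the same seed reproduce reports exactly.

## Known limitations

* NG86 per-gene ω is noisy at low divergence; cohort means of per-gene
  ratios are slightly biased upward by small synonymous denominators
  (visible as conserved-cohort means a few hundredths above the planted
  value at default divergence).
* The spliced aligner is a desk-scale reimplementation tuned for remnant
  recovery, not a general gene predictor; its intron state handles the
  single short intron the generator can plant, not many-exon structures.
* Remnant expression requires counts rows keyed by the locus id the gene
  would have carried; otherwise remnant TPM is reported unavailable.
* The paired specificity t-test needs two matched polyploids; the default
  synthetic dataset has one, so the pipeline exposes the per-chromosome
  table and the test as a library function.
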
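"""Synthetic allopolyploid datasets with planted truth.

The generator emulates the evolutionary scenario the downstream analyses
assume: two deeply diverged diploid progenitor genomes (``Bd``-like and
``Bs``-like), an allopolyploid carrying one subgenome sampled from each
(``BhD``/``BhS`` chromosomes inside a single ``Bhyb`` assembly), and an
outgroup.  Gene content is perfectly syntenic by construction — every
ancestral gene occupies the same rank on the corresponding chromosome of
every unit — so that the synteny walk has a well-defined truth to recover.

Planted signals
---------------
* a configurable fraction of polyploid genes per subgenome are pseudogenized:
  their sequence stays in the genome (the remnant interval is recorded in the
  truth table) but they are removed from the polyploid annotation and
  orthogroup column; lesions are nonsense codons, an internal deletion,
  and/or transcriptional silencing,
* conserved genes evolve under a strongly purifying dN/dS (default 0.2),
  pseudogenes under a relaxed one (default 0.5),
* TE families with controlled subgenome specificity,
* intact-LTR pairs of known insertion ages,
* negative-binomial expression counts with a controlled fraction of homeolog
  pairs favoring the D subgenome.

Everything is a deterministic function of the seed: the same seed produces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from Bio.Seq import Seq

from .io_formats import (GeneModel, GenomeUnit, LTRPair, TECopy, UnitMap,
                         write_counts, write_fasta, write_gff3, write_ltr_pairs,
                         write_orthogroups, write_te_table, Orthogroup)

import pandas as pd

# genetic code -------------------------------------------------------------

_BASES = "ACGT"
CODON2AA: dict[str, str] = {}
for _a in _BASES:
    for _b in _BASES:
        for _c in _BASES:
            cod = _a + _b + _c
            CODON2AA[cod] = str(Seq(cod).translate())
SENSE_CODONS = sorted(c for c, aa in CODON2AA.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON2AA.items() if aa == "*")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def translate_cds(cds: str) -> str:
    """Translate in frame 0, tolerating an incomplete terminal codon."""
    n = len(cds) - len(cds) % 3
    return "".join(CODON2AA.get(cds[i:i + 3], "X") for i in range(0, n, 3))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the generative model.  Defaults are the package's standard
    desk-scale study conditions (see docs/methods.md for rationale)."""

    seed: int = 0
    n_chromosomes_per_unit: int = 2
    n_genes_per_chromosome: int = 175
    mean_cds_codons: int = 300
    sd_cds_codons: int = 60
    min_cds_codons: int = 150
    max_cds_codons: int = 600
    intergenic_bp: int = 2000                 # mean intergap length
    kappa: float = 2.0                        # transition/transversion ratio
    progenitor_divergence: float = 0.12       # subs/site between D and S ancestors
    subgenome_divergence: float = 0.05        # subs/site subgenome vs progenitor
    outgroup_divergence: float = 0.30
    conserved_omega: float = 0.2
    pseudogene_omega: float = 0.5
    pseudogene_fraction_per_subgenome: float = 0.08
    pseudogene_nonsense_prob: float = 0.6
    pseudogene_deletion_prob: float = 0.5
    pseudogene_deletion_bp_mean: float = 150.0
    pseudogene_silencing_prob: float = 0.8
    outgroup_missing_fraction: float = 0.10
    intron_prob: float = 0.0                  # plant one short intron per gene
    intron_bp: int = 120
    # transposable elements
    n_te_families: int = 24
    te_copies_per_family_range: tuple[int, int] = (3, 30)
    te_subgenome_specific_fraction: float = 0.5
    te_len_range: tuple[int, int] = (300, 5000)
    te_gene_overlap_fraction: float = 0.25
    # intact LTR retrotransposons
    ltr_length_bp: int = 1000
    ltr_ages_years: tuple[float, ...] = (140_000.0, 1_400_000.0)
    ltr_pairs_per_age: int = 100
    n_ltr_families: int = 8
    substitution_rate_per_year: float = 1.3e-8
    # expression
    tissues: tuple[str, ...] = ("leaf", "root", "floret", "callus")
    library_size: int = 2_000_000
    nb_dispersion: float = 0.1
    homeolog_bias: float = 0.5                # fraction of pairs favoring D
    bias_effect: float = 3.0                  # mean ratio favored/unfavored
    remnant_expression_factor: float = 0.2

    def validate(self) -> None:
        probs = [self.pseudogene_fraction_per_subgenome,
                 self.pseudogene_nonsense_prob, self.pseudogene_deletion_prob,
                 self.pseudogene_silencing_prob, self.outgroup_missing_fraction,
                 self.intron_prob, self.te_subgenome_specific_fraction,
                 self.te_gene_overlap_fraction, self.homeolog_bias]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        rates = [self.kappa, self.substitution_rate_per_year, self.bias_effect]
        if any(r <= 0 for r in rates):
            raise ValueError("rates must be > 0")


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

NOT_PLANTED = "not_planted"


@dataclass
class PlantedPseudogene:
    gene_id: str          # the gene id the locus would have carried
    og_id: str
    unit_id: str
    chromosome: str
    start: int            # remnant interval on the polyploid assembly
    end: int
    diploid_gene_id: str
    nonsense_codons: list[int]
    deletion_spans: list[tuple[int, int]]   # bp offsets within the original CDS
    silenced: bool
    omega: float


@dataclass
class TruthTable:
    pseudogenes: dict[str, PlantedPseudogene] = field(default_factory=dict)
    pseudogene_by_og: dict[str, str] = field(default_factory=dict)
    conserved_genes: set[str] = field(default_factory=set)
    gene_omega: dict[str, float] = field(default_factory=dict)
    te_families: dict[str, str] = field(default_factory=dict)
    te_family_bp: dict[str, int] = field(default_factory=dict)
    ltr_ages: dict[str, float] = field(default_factory=dict)
    pair_favored: dict[str, str] = field(default_factory=dict)


def truth_lookup(truth: TruthTable, query_id: str) -> Any:
    """Return the planted record for an id, ``NOT_PLANTED`` for a conserved
    gene, or raise KeyError."""
    if query_id in truth.pseudogenes:
        return truth.pseudogenes[query_id]
    if query_id in truth.pseudogene_by_og:
        return truth.pseudogenes[truth.pseudogene_by_og[query_id]]
    if query_id in truth.conserved_genes:
        return NOT_PLANTED
    if query_id in truth.te_families:
        return truth.te_families[query_id]
    if query_id in truth.ltr_ages:
        return truth.ltr_ages[query_id]
    if query_id in truth.pair_favored:
        return truth.pair_favored[query_id]
    raise KeyError(f"unknown id {query_id!r} in truth table")


# ---------------------------------------------------------------------------
# sequence evolution primitives
# ---------------------------------------------------------------------------

def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _propose_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    r = rng.random() * (kappa + 2.0)
    if r < kappa:
        return _TRANSITION[base]
    others = [b for b in _BASES if b != base and b != _TRANSITION[base]]
    return others[0] if r < kappa + 1.0 else others[1]


def mutate_cds(cds: str, divergence: float, omega: float, kappa: float,
               rng: np.random.Generator, allow_stop: bool = False) -> str:
    """Codon-wise divergence: every site mutates with probability
    ``divergence``; proposed nonsynonymous changes are accepted with
    probability ``omega``, synonymous ones always.  Proposals creating a stop
    codon are rejected unless ``allow_stop``.  The start codon and the
    terminal stop are held fixed."""
    seq = list(cds)
    lo, hi = 3, len(seq) - 3
    hits = np.nonzero(rng.random(hi - lo) < divergence)[0] + lo
    for pos in hits:
        newb = _propose_base(seq[pos], kappa, rng)
        ci = (pos // 3) * 3
        codon = seq[ci:ci + 3]
        old_aa = CODON2AA["".join(codon)]
        codon[pos - ci] = newb
        new_aa = CODON2AA["".join(codon)]
        if new_aa == "*" and not allow_stop:
            continue
        if new_aa != old_aa and old_aa != "*" and rng.random() > omega:
            continue
        seq[pos] = newb
    return "".join(seq)


def mutate_by_events(seq: str, expected_subs_per_site: float, kappa: float,
                     rng: np.random.Generator) -> str:
    """Apply a Poisson number of substitution events (multiple hits allowed):
    the model under which a multiple-hit-corrected distance is unbiased."""
    out = list(seq)
    n_events = rng.poisson(expected_subs_per_site * len(out))
    for pos in rng.integers(0, len(out), size=n_events):
        out[pos] = _propose_base(out[pos], kappa, rng)
    return "".join(out)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def default_units() -> UnitMap:
    return UnitMap([
        GenomeUnit("Bd", "diploid", "Bd", ("Bd",)),
        GenomeUnit("Bs", "diploid", "Bs", ("Bs",)),
        GenomeUnit("BhD", "subgenome", "Bhyb", ("BhD",)),
        GenomeUnit("BhS", "subgenome", "Bhyb", ("BhS",)),
        GenomeUnit("Os", "outgroup", "Os", ("Os",)),
    ])


SUBGENOME_TO_PROGENITOR = {"BhD": "Bd", "BhS": "Bs"}

_ASSEMBLIES = {"Bd": ["Bd"], "Bs": ["Bs"], "Bhyb": ["BhD", "BhS"], "Os": ["Os"]}


@dataclass
class _GeneRecord:
    gene_id: str
    unit: str
    cds: str            # coding sequence (no intron)
    genomic: str        # forward-strand genomic sequence of the locus
    strand: str
    exons_rel: list[tuple[int, int]]   # relative to locus start, forward strand
    annotated: bool


def generate_dataset(config: SimulationConfig, out_dir: str | Path,
                     ) -> tuple[dict[str, Path], TruthTable]:
    """Write a complete fixture set under ``out_dir`` and return
    ``(paths, truth)``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    unit_map = default_units()

    C, G = config.n_chromosomes_per_unit, config.n_genes_per_chromosome

    # --- choose pseudogene slots (away from chromosome ends, flanks intact)
    margin = 6
    pseudo_slots: dict[str, set[tuple[int, int]]] = {"BhD": set(), "BhS": set()}
    k_pseudo = int(round(config.pseudogene_fraction_per_subgenome * C * G))
    eligible = [(c, i) for c in range(C) for i in range(margin, G - margin)]
    # disjoint between subgenomes: a planted loss is single-missing by design
    picks = rng.choice(len(eligible), size=2 * k_pseudo, replace=False)
    pseudo_slots["BhD"] = {eligible[int(p)] for p in picks[:k_pseudo]}
    pseudo_slots["BhS"] = {eligible[int(p)] for p in picks[k_pseudo:]}

    # outgroup-missing slots, disjoint from pseudogene slots
    blocked = pseudo_slots["BhD"] | pseudo_slots["BhS"]
    free = [s for s in [(c, i) for c in range(C) for i in range(G)]
            if s not in blocked]
    k_os = int(round(config.outgroup_missing_fraction * C * G))
    os_missing = {free[int(p)] for p in
                  rng.choice(len(free), size=min(k_os, len(free)), replace=False)}

    # --- evolve gene content
    # records[assembly][chrom_label] = list of _GeneRecord in positional order
    records: dict[str, dict[str, list[_GeneRecord | None]]] = {
        a: {} for a in _ASSEMBLIES}
    orthogroups: list[Orthogroup] = []
    unit_ids = [u.unit_id for u in unit_map.units]

    half = config.progenitor_divergence / 2.0

    for c in range(C):
        per_chrom: dict[str, list[_GeneRecord | None]] = {
            "Bd": [], "Bs": [], "BhD": [], "BhS": [], "Os": []}
        for i in range(G):
            og_id = f"OG{c + 1:02d}{i + 1:04d}"
            n_codons = int(np.clip(round(rng.normal(config.mean_cds_codons,
                                                    config.sd_cds_codons)),
                                   config.min_cds_codons, config.max_cds_codons))
            anc = _random_cds(n_codons, rng)
            d_anc = mutate_cds(anc, half, config.conserved_omega, config.kappa, rng)
            s_anc = mutate_cds(anc, half, config.conserved_omega, config.kappa, rng)

            members: dict[str, list[str]] = {u: [] for u in unit_ids}

            def _mk(unit: str, cds: str, annotated: bool = True) -> _GeneRecord:
                gid = f"{unit}_{c + 1:02d}g{i + 1:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                genomic, exons = cds, [(0, len(cds))]
                if annotated and strand == "+" and rng.random() < config.intron_prob:
                    k = 3 * (1 + int(rng.integers(len(cds) // 3 - 2)))
                    intron = "GT" + _random_dna(config.intron_bp - 4, rng) + "AG"
                    genomic = cds[:k] + intron + cds[k:]
                    exons = [(0, k), (k + len(intron), len(genomic))]
                if strand == "-":
                    genomic = _revcomp(genomic)
                return _GeneRecord(gid, unit, cds, genomic, strand, exons, annotated)

            per_chrom["Bd"].append(_mk("Bd", d_anc))
            per_chrom["Bs"].append(_mk("Bs", s_anc))
            members["Bd"] = [per_chrom["Bd"][-1].gene_id]
            members["Bs"] = [per_chrom["Bs"][-1].gene_id]

            for sub, prog_cds in (("BhD", d_anc), ("BhS", s_anc)):
                is_pseudo = (c, i) in pseudo_slots[sub]
                omega = config.pseudogene_omega if is_pseudo else config.conserved_omega
                # stops enter pseudogenes only through planted nonsense
                # lesions, so the truth table is the exact PTC indicator
                sub_cds = mutate_cds(prog_cds, config.subgenome_divergence,
                                     omega, config.kappa, rng)
                if is_pseudo:
                    sub_cds, lesions = _apply_lesions(sub_cds, config, rng)
                    rec = _mk(sub, sub_cds, annotated=False)
                    rec.exons_rel = [(0, len(rec.genomic))]
                    per_chrom[sub].append(rec)
                    prog_unit = SUBGENOME_TO_PROGENITOR[sub]
                    truth.pseudogenes[rec.gene_id] = PlantedPseudogene(
                        gene_id=rec.gene_id, og_id=og_id, unit_id=sub,
                        chromosome="", start=-1, end=-1,
                        diploid_gene_id=f"{prog_unit}_{c + 1:02d}g{i + 1:04d}",
                        nonsense_codons=lesions["nonsense"],
                        deletion_spans=lesions["deletions"],
                        silenced=lesions["silenced"], omega=omega)
                    truth.pseudogene_by_og[og_id] = rec.gene_id
                else:
                    rec = _mk(sub, sub_cds)
                    per_chrom[sub].append(rec)
                    members[sub] = [rec.gene_id]
                    truth.conserved_genes.add(rec.gene_id)
                    truth.gene_omega[rec.gene_id] = omega

            if (c, i) in os_missing:
                per_chrom["Os"].append(None)
            else:
                os_cds = mutate_cds(anc, config.outgroup_divergence,
                                    config.conserved_omega, config.kappa, rng)
                per_chrom["Os"].append(_mk("Os", os_cds))
                members["Os"] = [per_chrom["Os"][-1].gene_id]

            orthogroups.append(Orthogroup(og_id=og_id, members=members))

        # chromosome label = unit prefix + chromosome number
        for assembly, units in _ASSEMBLIES.items():
            for u in units:
                records[assembly].setdefault(f"{u}{c + 1}", []).extend(per_chrom[u])

    # --- lay out chromosomes, collect gene models / sequences / intergaps
    genomes: dict[str, dict[str, str]] = {a: {} for a in _ASSEMBLIES}
    gene_models: dict[str, list[GeneModel]] = {a: [] for a in _ASSEMBLIES}
    cds_fastas: dict[str, dict[str, str]] = {a: {} for a in _ASSEMBLIES}
    pep_fastas: dict[str, dict[str, str]] = {a: {} for a in _ASSEMBLIES}
    intergaps: dict[str, list[tuple[str, int, int]]] = {a: [] for a in _ASSEMBLIES}

    lo_gap = max(200, int(config.intergenic_bp * 0.6))
    hi_gap = int(config.intergenic_bp * 1.4)

    for assembly in _ASSEMBLIES:
        for chrom, recs in records[assembly].items():
            parts: list[str] = []
            pos = 0
            unit = chrom.rstrip("0123456789")
            for rec in recs:
                gap = int(rng.integers(lo_gap, hi_gap))
                parts.append(_random_dna(gap, rng))
                intergaps[assembly].append((chrom, pos, pos + gap))
                pos += gap
                if rec is None:
                    continue
                start, end = pos, pos + len(rec.genomic)
                parts.append(rec.genomic)
                pos = end
                if rec.annotated:
                    exons = [(start + s, start + e) for s, e in rec.exons_rel]
                    gene_models[assembly].append(GeneModel(
                        gene_id=rec.gene_id, unit_id=rec.unit, chromosome=chrom,
                        start=start, end=end, strand=rec.strand,
                        primary_transcript_length=len(rec.cds), exons=exons))
                    cds_fastas[assembly][rec.gene_id] = rec.cds
                    pep_fastas[assembly][rec.gene_id] = translate_cds(rec.cds)[:-1]
                elif rec.gene_id in truth.pseudogenes:
                    pg = truth.pseudogenes[rec.gene_id]
                    pg.chromosome, pg.start, pg.end = chrom, start, end
            tail = int(rng.integers(lo_gap, hi_gap))
            parts.append(_random_dna(tail, rng))
            intergaps[assembly].append((chrom, pos, pos + tail))
            genomes[assembly][chrom] = "".join(parts)

    # --- transposable elements on the polyploid
    te_copies = _plant_tes(config, rng, truth, intergaps["Bhyb"],
                           gene_models["Bhyb"], genomes["Bhyb"], unit_map)

    # --- intact LTR pairs
    ltr_pairs = _plant_ltrs(config, rng, truth)

    # --- homeolog pairs and expression counts
    pairs_df, counts_df = _plant_expression(config, rng, truth, orthogroups,
                                            gene_models["Bhyb"])

    # --- write everything
    paths: dict[str, Path] = {}
    for assembly in _ASSEMBLIES:
        paths[f"{assembly}.genome"] = out / f"{assembly}.genome.fa"
        write_fasta(genomes[assembly], paths[f"{assembly}.genome"])
        paths[f"{assembly}.gff3"] = out / f"{assembly}.genes.gff3"
        write_gff3(gene_models[assembly], paths[f"{assembly}.gff3"])
        paths[f"{assembly}.cds"] = out / f"{assembly}.cds.fa"
        write_fasta(cds_fastas[assembly], paths[f"{assembly}.cds"])
        paths[f"{assembly}.pep"] = out / f"{assembly}.pep.fa"
        write_fasta(pep_fastas[assembly], paths[f"{assembly}.pep"])
    paths["orthogroups"] = out / "orthogroups.tsv"
    write_orthogroups(orthogroups, unit_map, paths["orthogroups"])
    paths["pairs"] = out / "homeolog_pairs.tsv"
    pairs_df.to_csv(paths["pairs"], sep="\t", index=False)
    paths["te"] = out / "te_copies.tsv"
    write_te_table(te_copies, paths["te"])
    paths["ltr"] = out / "ltr_pairs.fa"
    write_ltr_pairs(ltr_pairs, paths["ltr"])
    paths["counts"] = out / "counts.tsv"
    write_counts(counts_df, paths["counts"])
    paths["truth"] = out / "truth_table.tsv"
    _write_truth(truth, paths["truth"])
    paths["config"] = out / "config.yaml"
    _write_run_config(config, out, paths)
    return paths, truth


def _apply_lesions(cds: str, config: SimulationConfig,
                   rng: np.random.Generator) -> tuple[str, dict]:
    """Nonsense codons, one internal deletion, and/or silencing."""
    lesions: dict[str, Any] = {"nonsense": [], "deletions": [], "silenced": False}
    n_codons = len(cds) // 3
    seq = cds
    if rng.random() < config.pseudogene_nonsense_prob:
        k = 1 + int(rng.poisson(0.5))
        # keep nonsense codons clear of the terminus: a stop in the last few
        # codons barely truncates the product and may fall outside the
        # alignable span, which would decouple the truth table from has_ptc
        codons = sorted(set(
            int(x) for x in rng.integers(2, max(3, n_codons - 8), size=k)))
        s = list(seq)
        for ci in codons:
            s[3 * ci:3 * ci + 3] = STOP_CODONS[int(rng.integers(3))]
        seq = "".join(s)
        lesions["nonsense"] = codons
    if rng.random() < config.pseudogene_deletion_prob:
        dlen = int(min(1 + rng.geometric(1.0 / config.pseudogene_deletion_bp_mean),
                       len(seq) // 2))
        start = int(rng.integers(3, len(seq) - dlen - 3))
        seq = seq[:start] + seq[start + dlen:]
        lesions["deletions"] = [(start, start + dlen)]
    lesions["silenced"] = bool(rng.random() < config.pseudogene_silencing_prob)
    return seq, lesions


def _plant_tes(config: SimulationConfig, rng: np.random.Generator,
               truth: TruthTable, intergaps: list[tuple[str, int, int]],
               genes: list[GeneModel], genome: dict[str, str],
               unit_map: UnitMap) -> list[TECopy]:
    class_pool = ["RLG", "RLC", "RIX", "DTM", "DTA", "DTH", "DHH", "RSX", "DTC"]
    class_w = np.array([0.30, 0.25, 0.12, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03])
    class_w = class_w / class_w.sum()
    gaps_by_unit: dict[str, list[tuple[str, int, int]]] = {"BhD": [], "BhS": []}
    for chrom, s, e in intergaps:
        unit = unit_map.unit_for(chrom)
        if unit in gaps_by_unit and e - s > 400:
            gaps_by_unit[unit].append((chrom, s, e))
    genes_by_unit: dict[str, list[GeneModel]] = {"BhD": [], "BhS": []}
    for g in genes:
        if g.unit_id in genes_by_unit:
            genes_by_unit[g.unit_id].append(g)

    n_specific = int(round(config.te_subgenome_specific_fraction
                           * config.n_te_families))
    order = rng.permutation(config.n_te_families)
    specific_ids = set(int(x) for x in order[:n_specific])

    copies: list[TECopy] = []
    lo, hi = config.te_copies_per_family_range
    for f in range(config.n_te_families):
        family = f"TEFAM{f + 1:03d}"
        klass = class_pool[int(rng.choice(len(class_pool), p=class_w))]
        n = int(rng.integers(lo, hi + 1))
        if f in specific_ids and n >= 5:
            major = "BhD" if rng.random() < 0.5 else "BhS"
            n_minor = int(rng.integers(0, n // 10 + 1))   # share >= 0.9 guaranteed
            units = [major] * (n - n_minor) + \
                    [("BhS" if major == "BhD" else "BhD")] * n_minor
            truth.te_families[family] = f"{'D' if major == 'BhD' else 'S'}-specific"
        elif f in specific_ids:
            major = "BhD" if rng.random() < 0.5 else "BhS"
            units = [major] * n
            truth.te_families[family] = "ineligible"
        else:
            n_d = n // 2
            units = ["BhD"] * n_d + ["BhS"] * (n - n_d)
            truth.te_families[family] = "shared" if n >= 5 else "ineligible"
        fam_bp = 0
        for k, unit in enumerate(units):
            te_len = int(rng.integers(*config.te_len_range))
            if rng.random() < config.te_gene_overlap_fraction:
                g = genes_by_unit[unit][int(rng.integers(len(genes_by_unit[unit])))]
                start = int(rng.integers(max(0, g.start - te_len + 50),
                                         max(1, g.end - 50)))
                chrom = g.chromosome
            else:
                gaps = gaps_by_unit[unit]
                widths = np.array([e - s for _, s, e in gaps], dtype=float)
                gi = int(rng.choice(len(gaps), p=widths / widths.sum()))
                chrom, gs, ge = gaps[gi]
                te_len = min(te_len, ge - gs - 2)
                start = gs + int(rng.integers(0, ge - gs - te_len))
            end = min(start + te_len, len(genome[chrom]))
            n_frag = 2 if rng.random() < 0.05 else 1
            length_bp = int((end - start) * 0.8) if n_frag == 2 else end - start
            copies.append(TECopy(
                copy_id=f"{family}.c{k + 1:03d}", family_id=family,
                class_code=klass, unit_id=unit, chromosome=chrom,
                start=start, end=end, strand="+" if rng.random() < 0.5 else "-",
                n_fragments=n_frag, length_bp=length_bp))
            fam_bp += length_bp
        truth.te_family_bp[family] = fam_bp
    if not copies:
        raise ValueError("no TE copies placed; intergenic space too small — "
                         "increase intergenic_bp or reduce te_len_range")
    return copies


def _plant_ltrs(config: SimulationConfig, rng: np.random.Generator,
                truth: TruthTable) -> list[LTRPair]:
    pairs: list[LTRPair] = []
    t = config.substitution_rate_per_year
    k = 0
    for age in config.ltr_ages_years:
        subs = age * t
        for _ in range(config.ltr_pairs_per_age):
            k += 1
            unit = "BhD" if rng.random() < 0.5 else "BhS"
            fam = f"LTRFAM{int(rng.integers(config.n_ltr_families)) + 1:02d}"
            anc = _random_dna(config.ltr_length_bp, rng)
            five = mutate_by_events(anc, subs, config.kappa, rng)
            three = mutate_by_events(anc, subs, config.kappa, rng)
            element = f"{unit}:LTR{k:04d}#{fam}"
            pairs.append(LTRPair(element_id=element, unit_id=unit,
                                 ltr5_sequence=five, ltr3_sequence=three,
                                 family_id=fam))
            truth.ltr_ages[element] = age
    return pairs


def _plant_expression(config: SimulationConfig, rng: np.random.Generator,
                      truth: TruthTable, orthogroups: list[Orthogroup],
                      bhyb_genes: list[GeneModel],
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    annotated = {g.gene_id for g in bhyb_genes}
    pair_rows = []
    lam: dict[str, float] = {}
    for og in orthogroups:
        d = og.members.get("BhD", [])
        s = og.members.get("BhS", [])
        base = float(rng.lognormal(math.log(30.0), 1.0))
        if d and s and d[0] in annotated and s[0] in annotated:
            favored = "D" if rng.random() < config.homeolog_bias else "S"
            pair_rows.append({"d_gene": d[0], "s_gene": s[0]})
            truth.pair_favored[f"{d[0]}|{s[0]}"] = favored
            lam[d[0]] = base * (config.bias_effect if favored == "D" else 1.0)
            lam[s[0]] = base * (config.bias_effect if favored == "S" else 1.0)
        else:
            for gid in d + s:
                if gid in annotated:
                    lam[gid] = base
    # unannotated remnants: low or zero expression
    for gid, pg in truth.pseudogenes.items():
        lam[gid] = 0.0 if pg.silenced else \
            float(rng.lognormal(math.log(30.0), 1.0)) * config.remnant_expression_factor

    gene_ids = sorted(lam)
    mu0 = np.array([lam[g] for g in gene_ids])
    counts = {}
    r = 1.0 / config.nb_dispersion
    for tissue in config.tissues:
        factor = rng.lognormal(0.0, 0.2, size=len(gene_ids))
        mu = mu0 * factor
        if mu.sum() > 0:
            mu = mu * (config.library_size / mu.sum())
        p = r / (r + mu)
        counts[tissue] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    return pd.DataFrame(pair_rows, columns=["d_gene", "s_gene"]), counts_df


def _write_truth(truth: TruthTable, path: Path) -> None:
    rows = []
    for gid, pg in sorted(truth.pseudogenes.items()):
        rows.append({"kind": "pseudogene", "id": gid,
                     "payload": json.dumps(dataclasses.asdict(pg), sort_keys=True)})
    for gid in sorted(truth.conserved_genes):
        rows.append({"kind": "conserved_gene", "id": gid, "payload": ""})
    for fam, label in sorted(truth.te_families.items()):
        rows.append({"kind": "te_family", "id": fam, "payload": label})
    for el, age in truth.ltr_ages.items():
        rows.append({"kind": "ltr_age", "id": el, "payload": repr(age)})
    for pair, fav in sorted(truth.pair_favored.items()):
        rows.append({"kind": "pair_favored", "id": pair, "payload": fav})
    pd.DataFrame(rows, columns=["kind", "id", "payload"]).to_csv(
        path, sep="\t", index=False)


def load_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    truth = TruthTable()
    for row in df.itertuples(index=False):
        if row.kind == "pseudogene":
            d = json.loads(row.payload)
            d["deletion_spans"] = [tuple(x) for x in d["deletion_spans"]]
            pg = PlantedPseudogene(**d)
            truth.pseudogenes[pg.gene_id] = pg
            truth.pseudogene_by_og[pg.og_id] = pg.gene_id
        elif row.kind == "conserved_gene":
            truth.conserved_genes.add(row.id)
        elif row.kind == "te_family":
            truth.te_families[row.id] = row.payload
        elif row.kind == "ltr_age":
            truth.ltr_ages[row.id] = float(row.payload)
        elif row.kind == "pair_favored":
            truth.pair_favored[row.id] = row.payload
    return truth


def _write_run_config(config: SimulationConfig, out: Path,
                      paths: dict[str, Path]) -> None:
    cfg = {
        "units": [
            {"unit_id": u.unit_id, "role": u.role, "parent_genome": u.parent_genome,
             "chromosome_patterns": list(u.chromosome_patterns)}
            for u in default_units().units],
        "subgenome_to_progenitor": dict(SUBGENOME_TO_PROGENITOR),
        "polyploid": "Bhyb",
        "tissues": list(config.tissues),
        "files": {k: str(v.name) for k, v in paths.items() if k != "config"},
        "simulation": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
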
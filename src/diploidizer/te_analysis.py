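"""Transposable-element analyses: composition summaries, subgenome-specific
family classification, gene-TE proximity statistics, and intact-LTR
insertion dating.

Insertion dating follows the standard intact-LTR clock: the two long
terminal repeats of an element are identical at insertion, so their current
divergence D (Kimura 2-parameter corrected, distinguishing transition
proportion P from transversion proportion Q) divided by twice the per-year
substitution rate t gives the time since insertion, T = D / (2 t).  The
default rate is 1.3e-8 substitutions/site/year.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .io_formats import GeneModel, LTRPair, TECopy

DEFAULT_SUBSTITUTION_RATE = 1.3e-8
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition_summary(te_copies: Sequence[TECopy]) -> pd.DataFrame:
    """Per-unit, per-class copy counts and bp totals, plus Gypsy:Copia copy-
    and mean-length ratios (reported where both classes are present)."""
    if not te_copies:
        return pd.DataFrame(columns=["unit_id", "class_code", "n_copies",
                                     "total_bp", "mean_length_bp"])
    df = pd.DataFrame([{"unit_id": t.unit_id, "class_code": t.class_code,
                        "length_bp": t.length_bp} for t in te_copies])
    out = (df.groupby(["unit_id", "class_code"])
             .agg(n_copies=("length_bp", "size"), total_bp=("length_bp", "sum"),
                  mean_length_bp=("length_bp", "mean"))
             .reset_index())
    return out


def gypsy_copia_ratios(summary: pd.DataFrame,
                       gypsy: str = "RLG", copia: str = "RLC",
                       ) -> pd.DataFrame:
    rows = []
    for unit, sub in summary.groupby("unit_id"):
        g = sub[sub.class_code == gypsy]
        c = sub[sub.class_code == copia]
        if len(g) and len(c) and c.n_copies.iloc[0] > 0:
            rows.append({
                "unit_id": unit,
                "copy_ratio": g.n_copies.iloc[0] / c.n_copies.iloc[0],
                "mean_length_ratio": g.mean_length_bp.iloc[0] / c.mean_length_bp.iloc[0],
            })
    return pd.DataFrame(rows, columns=["unit_id", "copy_ratio", "mean_length_ratio"])


# ---------------------------------------------------------------------------
# subgenome specificity
# ---------------------------------------------------------------------------

@dataclass
class TEFamilySummary:
    family_id: str
    n_copies: int
    copies_per_unit: dict[str, int]
    specificity: str   # "D-specific" | "S-specific" | "shared" | "ineligible"
    per_chromosome: dict[str, int] = field(default_factory=dict)


def classify_specificity(te_copies: Sequence[TECopy], d_unit: str, s_unit: str,
                         min_copies: int = 5, threshold: float = 0.90,
                         ) -> tuple[list[TEFamilySummary], float, pd.DataFrame]:
    """Label families subgenome-specific when they have >= ``min_copies``
    copies and >= ``threshold`` (inclusive) of them on one subgenome.

    Returns (family summaries, genome-level % of copies in specific families,
    per-chromosome % table).
    """
    fams: dict[str, list[TECopy]] = defaultdict(list)
    for te in te_copies:
        if te.unit_id in (d_unit, s_unit):
            fams[te.family_id].append(te)
    summaries: list[TEFamilySummary] = []
    specific_families: set[str] = set()
    for family in sorted(fams):
        copies = fams[family]
        per_unit = {d_unit: sum(1 for t in copies if t.unit_id == d_unit),
                    s_unit: sum(1 for t in copies if t.unit_id == s_unit)}
        per_chrom: dict[str, int] = defaultdict(int)
        for t in copies:
            per_chrom[t.chromosome] += 1
        n = len(copies)
        if n < min_copies:
            spec = "ineligible"
        elif per_unit[d_unit] / n >= threshold:
            spec = "D-specific"
        elif per_unit[s_unit] / n >= threshold:
            spec = "S-specific"
        else:
            spec = "shared"
        if spec.endswith("-specific"):
            specific_families.add(family)
        summaries.append(TEFamilySummary(family_id=family, n_copies=n,
                                         copies_per_unit=per_unit,
                                         specificity=spec,
                                         per_chromosome=dict(per_chrom)))
    all_copies = [t for c in fams.values() for t in c]
    n_total = len(all_copies)
    n_spec = sum(1 for t in all_copies if t.family_id in specific_families)
    pct = 100.0 * n_spec / n_total if n_total else 0.0
    rows = []
    for chrom in sorted({t.chromosome for t in all_copies}):
        on_chrom = [t for t in all_copies if t.chromosome == chrom]
        k = sum(1 for t in on_chrom if t.family_id in specific_families)
        rows.append({"chromosome": chrom, "n_copies": len(on_chrom),
                     "pct_specific": 100.0 * k / len(on_chrom)})
    return summaries, pct, pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False   # zero-variance differences


def specificity_paired_test(per_chromosome_pct_a: Sequence[float],
                            per_chromosome_pct_b: Sequence[float],
                            ) -> PairedTestResult:
    """Paired t-test of matched chromosome-level percentages (two-sided)."""
    a = np.asarray(per_chromosome_pct_a, dtype=float)
    b = np.asarray(per_chromosome_pct_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTestResult(t_statistic=0.0, p_value=1.0, n=a.size,
                                    degenerate=True)
        return PairedTestResult(t_statistic=math.inf * np.sign(diff.mean()),
                                p_value=0.0, n=a.size, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t_statistic=float(t), p_value=float(p), n=a.size)


# ---------------------------------------------------------------------------
# gene-TE proximity
# ---------------------------------------------------------------------------

@dataclass
class GeneTEStats:
    pct_genes_overlapping_te: float
    pct_exons_overlapping_te: float
    mean_te_gene_distance_bp: float
    n_genes: int
    n_exons: int
    n_tes: int
    by_compartment: dict[str, float] = field(default_factory=dict)


def _interval_overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def gene_te_overlap(genes: Sequence[GeneModel], te_copies: Sequence[TECopy],
                    compartments: Mapping[str, list[tuple[int, int, str]]] | None = None,
                    ) -> GeneTEStats:
    """Gene/exon overlap percentages (same-strand rule, intronic and UTR TEs
    count for the gene) and the mean strand-agnostic TE-to-nearest-gene
    distance (0 for overlapping)."""
    tes_by_chrom: dict[str, list[TECopy]] = defaultdict(list)
    for te in te_copies:
        tes_by_chrom[te.chromosome].append(te)
    genes_by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chromosome].append(g)

    n_gene_hit = n_exon = n_exon_hit = 0
    for g in genes:
        tes = [t for t in tes_by_chrom[g.chromosome] if t.strand == g.strand]
        hit = any(_interval_overlaps(g.start, g.end, t.start, t.end) for t in tes)
        n_gene_hit += hit
        for es, ee in (g.exons or [(g.start, g.end)]):
            n_exon += 1
            n_exon_hit += any(_interval_overlaps(es, ee, t.start, t.end)
                              for t in tes)

    # strand-agnostic envelope distance, TE -> nearest gene
    dists = []
    by_comp: dict[str, list[float]] = defaultdict(list)
    for chrom, tes in tes_by_chrom.items():
        gl = genes_by_chrom.get(chrom, [])
        if not gl:
            continue
        starts = np.array([g.start for g in gl])
        ends = np.array([g.end for g in gl])
        for te in tes:
            gap = np.maximum(0, np.maximum(starts - te.end, te.start - ends))
            d = float(gap.min())
            dists.append(d)
            if compartments and chrom in compartments:
                mid = (te.start + te.end) // 2
                for cs, ce, label in compartments[chrom]:
                    if cs <= mid < ce:
                        by_comp[label].append(d)
                        break
    n_genes = len(genes)
    return GeneTEStats(
        pct_genes_overlapping_te=100.0 * n_gene_hit / n_genes if n_genes else 0.0,
        pct_exons_overlapping_te=100.0 * n_exon_hit / n_exon if n_exon else 0.0,
        mean_te_gene_distance_bp=float(np.mean(dists)) if dists else 0.0,
        n_genes=n_genes, n_exons=n_exon, n_tes=len(te_copies),
        by_compartment={k: float(np.mean(v)) for k, v in sorted(by_comp.items())})


# ---------------------------------------------------------------------------
# intact-LTR dating
# ---------------------------------------------------------------------------

@dataclass
class DatedLTR:
    element_id: str
    unit_id: str
    family_id: str
    p_transitions: float
    q_transversions: float
    k2p_divergence: float
    insertion_time_years: float = float("nan")
    n_sites: int = 0


class K2PSaturationError(ValueError):
    pass


_LTR_ALIGNER = Align.PairwiseAligner()
_LTR_ALIGNER.mode = "global"
_LTR_ALIGNER.match_score = 1
_LTR_ALIGNER.mismatch_score = -1
_LTR_ALIGNER.open_gap_score = -4
_LTR_ALIGNER.extend_gap_score = -1


def k2p(pair: LTRPair) -> DatedLTR:
    """Kimura 2-parameter divergence between the two LTRs of one element.

    The LTRs are globally aligned; columns containing a gap or an N are
    removed before counting (the pairwise rendering of a gap-threshold
    trimming step).  D = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)).
    """
    aln = _LTR_ALIGNER.align(pair.ltr5_sequence, pair.ltr3_sequence)[0]
    a, b = str(aln[0]), str(aln[1])
    n_sites = ts = tv = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        n_sites += 1
        if ca != cb:
            if (ca, cb) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n_sites == 0:
        raise K2PSaturationError(f"{pair.element_id}: no comparable columns")
    P, Q = ts / n_sites, tv / n_sites
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PSaturationError(f"{pair.element_id}: saturated (P={P}, Q={Q})")
    D = -0.5 * math.log(w1 * math.sqrt(w2))
    return DatedLTR(element_id=pair.element_id, unit_id=pair.unit_id,
                    family_id=pair.family_id, p_transitions=P,
                    q_transversions=Q, k2p_divergence=D, n_sites=n_sites)


def insertion_time(D: float, rate: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """T = D / (2 t) years since insertion."""
    if D < 0:
        raise ValueError("divergence must be nonnegative")
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return D / (2.0 * rate)


def date_ltr_pairs(pairs: Sequence[LTRPair],
                   rate: float = DEFAULT_SUBSTITUTION_RATE,
                   ) -> tuple[list[DatedLTR], list[tuple[str, str]]]:
    """Date every element; saturated/uncomparable ones are excluded with a
    reason rather than silently dropped."""
    dated: list[DatedLTR] = []
    excluded: list[tuple[str, str]] = []
    for pair in pairs:
        try:
            d = k2p(pair)
        except K2PSaturationError as exc:
            excluded.append((pair.element_id, str(exc)))
            continue
        d.insertion_time_years = insertion_time(d.k2p_divergence, rate)
        dated.append(d)
    return dated, excluded


@dataclass
class FamilyAgeProfile:
    lifespans: dict[str, float]          # family -> max - min age (years)
    young_fraction_per_unit: dict[str, float]
    young_fraction: float
    age_threshold_years: float


def family_age_profile(dated_ltrs: Sequence[DatedLTR], min_intact: int = 2,
                       age_threshold_years: float = 1.4e6) -> FamilyAgeProfile:
    """Family lifespans (oldest minus youngest member; families with fewer
    than ``min_intact`` dated elements are excluded) and the fraction of
    elements younger than the threshold, overall and per unit."""
    by_fam: dict[str, list[float]] = defaultdict(list)
    by_unit: dict[str, list[float]] = defaultdict(list)
    ages = []
    for d in dated_ltrs:
        by_fam[d.family_id].append(d.insertion_time_years)
        by_unit[d.unit_id].append(d.insertion_time_years)
        ages.append(d.insertion_time_years)
    lifespans = {f: max(a) - min(a) for f, a in sorted(by_fam.items())
                 if len(a) >= min_intact}
    young = {u: float(np.mean(np.array(a) < age_threshold_years))
             for u, a in sorted(by_unit.items())}
    overall = float(np.mean(np.array(ages) < age_threshold_years)) if ages else 0.0
    return FamilyAgeProfile(lifespans=lifespans, young_fraction_per_unit=young,
                            young_fraction=overall,
                            age_threshold_years=age_threshold_years)
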
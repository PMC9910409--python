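"""Characterize candidate pseudogene regions: spliced alignment of the
diploid gene into the region, premature-termination-codon detection,
length deficit, pairwise dN/dS (NG86 counting with Jukes-Cantor correction),
expression, TE containment, and the conserved-gene resampling control.

dN/dS method
------------
Nei-Gojobori (1986)-style counting: per-codon synonymous/nonsynonymous site
fractions (mutations to stop codons excluded from the site normalization),
observed differences averaged over all shortest mutational pathways between
paired codons (pathways passing through a stop codon are dropped, falling
back to all pathways when every one is blocked), and the Jukes-Cantor
multiple-hit correction d = -(3/4) ln(1 - 4p/3) applied to the proportions.
omega = dN/dS is flagged invalid when dS = 0 or a proportion is saturated
(p >= 3/4) — alignments with no synonymous substitutions yield no ratio.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from . import _spliced
from .io_formats import GeneModel, TECopy
from .pseudogene_locator import CandidateRegion, LOCATED
from .synthetic_data import CODON2AA

STOPS = ("TAA", "TAG", "TGA")
MIN_PEPTIDE_AA = 10


# ---------------------------------------------------------------------------
# spliced alignment
# ---------------------------------------------------------------------------

@dataclass
class SplicedAlignment:
    og_id: str
    score: float
    strand: str                          # region strand carrying the gene
    chunks: list[tuple[str, str]]        # codon phase map, reading order
    inferred_cds: str                    # aligned nt, introns excluded
    exon_intervals: list[tuple[int, int]]  # forward-strand region coordinates
    aligned_protein_coverage: float
    pep_start: int = 0
    pep_end: int = 0

    @property
    def empty(self) -> bool:
        return self.aligned_protein_coverage == 0.0


def _empty_alignment(og_id: str) -> SplicedAlignment:
    return SplicedAlignment(og_id=og_id, score=0.0, strand="+", chunks=[],
                            inferred_cds="", exon_intervals=[],
                            aligned_protein_coverage=0.0)


def spliced_align(diploid_peptide: str, region_sequence: str,
                  og_id: str = "") -> SplicedAlignment:
    """Align a diploid peptide into a genomic region, both strands, all
    frames, with frameshift- and intron-tolerant gaps.

    Alignments scoring below a fixed fraction of the peptide's self-alignment
    score are reported empty (coverage 0): the region contains no alignable
    remnant.
    """
    if len(diploid_peptide) < MIN_PEPTIDE_AA:
        raise ValueError(f"peptide shorter than {MIN_PEPTIDE_AA} aa")
    fwd = _spliced.align_protein_to_dna(diploid_peptide, region_sequence)
    rev = _spliced.align_protein_to_dna(diploid_peptide,
                                        _spliced.revcomp(region_sequence))
    raw, strand = (fwd, "+") if fwd.score >= rev.score else (rev, "-")
    threshold = _spliced.SCORE_THRESHOLD_FRACTION * _spliced.self_score(diploid_peptide)
    if raw.score < threshold or not raw.chunks:
        return _empty_alignment(og_id)

    n = len(region_sequence)
    # exon intervals on the aligned strand, then mapped to forward coords
    exons: list[list[int]] = []
    pos = raw.dna_start
    for kind, payload in raw.chunks:
        if kind == "intron":
            pos += len(payload)
            continue
        if kind == "del":
            continue
        if not exons or exons[-1][1] != pos:
            exons.append([pos, pos + len(payload)])
        else:
            exons[-1][1] = pos + len(payload)
        pos += len(payload)
    if strand == "-":
        intervals = sorted((n - e, n - s) for s, e in exons)
    else:
        intervals = [(s, e) for s, e in exons]

    aligned_aa = sum(1 for kind, _ in raw.chunks if kind in ("codon", "fs"))
    inferred = "".join(p for kind, p in raw.chunks if kind in ("codon", "fs", "ins"))
    return SplicedAlignment(
        og_id=og_id, score=raw.score, strand=strand, chunks=raw.chunks,
        inferred_cds=inferred, exon_intervals=intervals,
        aligned_protein_coverage=aligned_aa / len(diploid_peptide),
        pep_start=raw.pep_start, pep_end=raw.pep_end)


def detect_ptc(alignment: SplicedAlignment) -> bool:
    """True iff an in-frame stop codon occurs before the final aligned codon.

    Codon phase comes from the alignment chunks, so codons disrupted by
    frameshifts are not misread as stops.
    """
    codon_idx = [k for k, (kind, _) in enumerate(alignment.chunks)
                 if kind == "codon"]
    if not codon_idx:
        return False
    last = codon_idx[-1]
    return any(alignment.chunks[k][1] in STOPS
               for k in codon_idx if k != last)


# ---------------------------------------------------------------------------
# codon-level alignment of diploid CDS vs inferred CDS
# ---------------------------------------------------------------------------

@dataclass
class CodonPair:
    codon_a: str
    codon_b: str
    frameshifted: bool


_NT_ALIGNER = Align.PairwiseAligner()
_NT_ALIGNER.mode = "global"
_NT_ALIGNER.match_score = 2
_NT_ALIGNER.mismatch_score = -3
_NT_ALIGNER.open_gap_score = -8
_NT_ALIGNER.extend_gap_score = -2


def codon_align(diploid_cds: str, inferred_cds: str) -> list[CodonPair]:
    """Thread paired codons through a global nucleotide alignment on the
    diploid reading frame.

    A codon is marked ``frameshifted`` (and excluded from substitution
    counting downstream) when the cumulative indel offset at its start is not
    a multiple of 3, or a gap falls inside its three columns — the situation
    a 1-bp indel creates for every downstream codon until a compensating
    indel restores the frame.
    """
    a, b = diploid_cds.upper(), inferred_cds.upper()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("cannot translate a sequence shorter than one codon")
    aln = _NT_ALIGNER.align(a, b)[0]
    arow, brow = str(aln[0]), str(aln[1])

    pairs: list[CodonPair] = []
    cod_a: list[str] = []
    cod_b: list[str] = []
    offset = 0            # (nt inserted in b) - (nt deleted from b), mod 3
    start_offset = 0
    gap_inside = False
    for ca, cb in zip(arow, brow):
        if ca == "-":
            offset += 1
            if cod_a:
                gap_inside = True
            continue
        if not cod_a:
            start_offset = offset
            gap_inside = False
        cod_a.append(ca)
        cod_b.append(cb)
        if cb == "-":
            offset -= 1
            gap_inside = True
        if len(cod_a) == 3:
            bc = "".join(cod_b)
            fs = (start_offset % 3 != 0) or gap_inside or "-" in bc
            pairs.append(CodonPair("".join(cod_a), bc, fs))
            cod_a, cod_b = [], []
    return pairs


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@lru_cache(maxsize=None)
def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon; changes
    producing stop codons are excluded and the position renormalized to 1."""
    aa = CODON2AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON2AA[alt] == "*":
                continue
            valid += 1
            if CODON2AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all shortest mutational pathways; pathways through a stop codon are
    dropped (all pathways used if every one is blocked)."""
    diff_pos = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_pos:
        return 0.0, 0.0
    results: list[tuple[float, float, bool]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if CODON2AA[nxt] == "*":
                through_stop = True
            if CODON2AA[nxt] == CODON2AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, through_stop))
    usable = [(sd, nd) for sd, nd, blocked in results if not blocked]
    if not usable:
        usable = [(sd, nd) for sd, nd, _ in results]
    return (sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable))


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); undefined (math domain) at p >= 3/4."""
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class DnDsResult:
    dn: float
    ds: float
    omega: float
    omega_valid: bool
    pn: float = 0.0
    ps: float = 0.0
    n_codons: int = 0
    saturated: bool = False


def dnds(codon_alignment: Sequence[CodonPair]) -> DnDsResult:
    """NG86 pairwise dN/dS over the paired, non-frameshifted, stop-free
    codons of a codon alignment."""
    S = N = Sd = Nd = 0.0
    n_used = 0
    for pair in codon_alignment:
        ca, cb = pair.codon_a, pair.codon_b
        if pair.frameshifted or len(cb) != 3:
            continue
        if set(ca + cb) - set(_BASES):
            continue
        if CODON2AA[ca] == "*" or CODON2AA[cb] == "*":
            continue
        sa, na = _site_fractions(ca)
        sb, nb = _site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable codon pairs in alignment")
    pn = Nd / N if N > 0 else 0.0
    ps = Sd / S if S > 0 else 0.0
    if pn >= 0.75 or ps >= 0.75:
        return DnDsResult(dn=float("nan"), ds=float("nan"), omega=float("nan"),
                          omega_valid=False, pn=pn, ps=ps, n_codons=n_used,
                          saturated=True)
    dn, ds = jukes_cantor(pn), jukes_cantor(ps)
    valid = ds > 0.0
    return DnDsResult(dn=dn, ds=ds, omega=dn / ds if valid else float("nan"),
                      omega_valid=valid, pn=pn, ps=ps, n_codons=n_used)


# ---------------------------------------------------------------------------
# per-candidate report
# ---------------------------------------------------------------------------

@dataclass
class PseudogeneReport:
    og_id: str
    gene_id: str                      # remnant/control gene identifier
    alignment_bp: int
    diploid_cds_bp: int
    length_deficit_bp: int            # 3 * peptide aa - alignment bp, signed
    has_ptc: bool
    dn: float = float("nan")
    ds: float = float("nan")
    omega: float = float("nan")
    omega_valid: bool = False
    coverage: float = 0.0
    tpm_per_tissue: dict[str, float] = field(default_factory=dict)
    nonexpressed_per_tissue: dict[str, bool] = field(default_factory=dict)
    te_contained: bool = False
    aligned: bool = True


def characterize(candidate: CandidateRegion, region_sequence: str,
                 diploid_cds: str, diploid_peptide: str,
                 te_copies: Sequence[TECopy] = (),
                 tpm_row: Mapping[str, float] | None = None,
                 gene_id: str = "") -> PseudogeneReport:
    """Assemble every per-gene metric for one located candidate region."""
    if candidate.status != LOCATED:
        raise ValueError(f"candidate {candidate.og_id} not located")
    aln = spliced_align(diploid_peptide, region_sequence, og_id=candidate.og_id)
    if aln.empty:
        return PseudogeneReport(
            og_id=candidate.og_id, gene_id=gene_id, alignment_bp=0,
            diploid_cds_bp=len(diploid_cds),
            length_deficit_bp=3 * len(diploid_peptide), has_ptc=False,
            aligned=False,
            tpm_per_tissue=dict(tpm_row) if tpm_row else {},
            nonexpressed_per_tissue={t: v == 0.0 for t, v in tpm_row.items()}
            if tpm_row else {})

    report = PseudogeneReport(
        og_id=candidate.og_id, gene_id=gene_id,
        alignment_bp=len(aln.inferred_cds), diploid_cds_bp=len(diploid_cds),
        length_deficit_bp=3 * len(diploid_peptide) - len(aln.inferred_cds),
        has_ptc=detect_ptc(aln), coverage=aln.aligned_protein_coverage)
    try:
        result = dnds(codon_align(diploid_cds, aln.inferred_cds))
        report.dn, report.ds = result.dn, result.ds
        report.omega, report.omega_valid = result.omega, result.omega_valid
    except ValueError:
        pass
    if te_copies and aln.exon_intervals:
        lo = candidate.start + aln.exon_intervals[0][0]
        hi = candidate.start + aln.exon_intervals[-1][1]
        report.te_contained = any(
            te.chromosome == candidate.target_chromosome
            and te.start < hi and te.end > lo           # strand-agnostic
            for te in te_copies)
    if tpm_row is not None:
        report.tpm_per_tissue = dict(tpm_row)
        report.nonexpressed_per_tissue = {t: v == 0.0 for t, v in tpm_row.items()}
    return report


def characterize_own_locus(gene: GeneModel, chrom_seq: str, diploid_cds: str,
                           diploid_peptide: str, flank_bp: int = 200,
                           te_copies: Sequence[TECopy] = (),
                           tpm_row: Mapping[str, float] | None = None,
                           ) -> PseudogeneReport:
    """Run the characterization procedure on an annotated gene's own locus —
    the conserved-control arm of the analysis."""
    start = max(0, gene.start - flank_bp)
    end = min(len(chrom_seq), gene.end + flank_bp)
    candidate = CandidateRegion(
        og_id=gene.gene_id, missing_unit=gene.unit_id,
        diploid_gene_id="", status=LOCATED, target_chromosome=gene.chromosome,
        start=start, end=end)
    return characterize(candidate, chrom_seq[start:end], diploid_cds,
                        diploid_peptide, te_copies=te_copies, tpm_row=tpm_row,
                        gene_id=gene.gene_id)


# ---------------------------------------------------------------------------
# resampling control
# ---------------------------------------------------------------------------

TRIAL_METRICS = ("mean_length_deficit", "ptc_fraction", "mean_omega",
                 "median_tpm", "te_contained_fraction")


@dataclass
class ControlDistribution:
    n_trials: int
    per_trial_d: int
    per_trial_s: int
    trials: pd.DataFrame                  # one row per trial
    tissues: tuple[str, ...] = ()

    def empirical_p(self, observed: float, metric: str,
                    direction: str = "greater") -> float:
        """(r+1)/(n+1) one-sided empirical p-value; never exactly zero."""
        vals = self.trials[metric].to_numpy()
        if direction == "greater":
            r = int((vals >= observed).sum())
        elif direction == "less":
            r = int((vals <= observed).sum())
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return (r + 1) / (len(vals) + 1)

    def expected_nonexpressed_freq(self, tissue: str) -> float:
        return float(self.trials[f"nonexpressed_{tissue}"].mean())


def _trial_metrics(reports: list[PseudogeneReport],
                   tissues: Sequence[str]) -> dict[str, float]:
    deficits = [r.length_deficit_bp for r in reports]
    omegas = [r.omega for r in reports if r.omega_valid]
    tpms = [float(np.mean(list(r.tpm_per_tissue.values())))
            for r in reports if r.tpm_per_tissue]
    row = {
        "mean_length_deficit": float(np.mean(deficits)),
        "ptc_fraction": float(np.mean([r.has_ptc for r in reports])),
        "mean_omega": float(np.mean(omegas)) if omegas else float("nan"),
        "median_tpm": float(np.median(tpms)) if tpms else float("nan"),
        "te_contained_fraction": float(np.mean([r.te_contained for r in reports])),
    }
    for t in tissues:
        flags = [r.nonexpressed_per_tissue.get(t, False) for r in reports
                 if r.nonexpressed_per_tissue]
        row[f"nonexpressed_{t}"] = float(np.mean(flags)) if flags else float("nan")
    return row


def control_trials(conserved_pool_d: list[PseudogeneReport],
                   conserved_pool_s: list[PseudogeneReport],
                   n_trials: int = 1000, per_trial_d: int = 224,
                   per_trial_s: int = 240, seed: int = 0,
                   tissues: Sequence[str] = ()) -> ControlDistribution:
    """Resample conserved-gene characterizations: each trial draws
    ``per_trial_d`` + ``per_trial_s`` genes without replacement (with
    replacement across trials) and recomputes every cohort metric."""
    if len(conserved_pool_d) < per_trial_d or len(conserved_pool_s) < per_trial_s:
        raise ValueError("conserved pools smaller than the per-trial draw")
    if not tissues:
        for r in conserved_pool_d + conserved_pool_s:
            if r.tpm_per_tissue:
                tissues = tuple(r.tpm_per_tissue)
                break
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_trials):
        pick_d = rng.choice(len(conserved_pool_d), size=per_trial_d, replace=False)
        pick_s = rng.choice(len(conserved_pool_s), size=per_trial_s, replace=False)
        sample = [conserved_pool_d[i] for i in pick_d] + \
                 [conserved_pool_s[i] for i in pick_s]
        rows.append(_trial_metrics(sample, tissues))
    return ControlDistribution(n_trials=n_trials, per_trial_d=per_trial_d,
                               per_trial_s=per_trial_s,
                               trials=pd.DataFrame(rows), tissues=tuple(tissues))


def nonexpression_enrichment(n_nonexpressed: int, n_total: int,
                             expected_freq: float) -> float:
    """One-sided exact binomial tail P(X >= observed | n, expected_freq)."""
    from scipy import stats
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if expected_freq <= 0.0:
        return 1.0 if n_nonexpressed == 0 else 0.0
    if expected_freq >= 1.0:
        return 1.0
    return float(stats.binomtest(n_nonexpressed, n_total, expected_freq,
                                 alternative="greater").pvalue)
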
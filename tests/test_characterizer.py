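"""Spliced alignment, PTC detection, codon threading, NG86 dN/dS against an
independent all-pathways oracle, and the resampling control."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from diploidizer.pseudogene_characterizer import (CodonPair, PseudogeneReport,
                                                  SplicedAlignment,
                                                  codon_align, control_trials,
                                                  detect_ptc, dnds,
                                                  nonexpression_enrichment,
                                                  spliced_align)
from diploidizer.synthetic_data import (_random_cds, mutate_cds,
                                        translate_cds)


def _rng(seed=0):
    return np.random.default_rng(seed)


def _random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# spliced alignment
# ---------------------------------------------------------------------------

class TestSplicedAlign:
    def test_exact_cds_recovered_with_full_coverage(self):
        rng = _rng(1)
        cds = _random_cds(120, rng)
        pep = translate_cds(cds)[:-1]
        region = _random_dna(400, rng) + cds + _random_dna(400, rng)
        a = spliced_align(pep, region)
        assert a.aligned_protein_coverage == 1.0
        assert a.inferred_cds == cds[:3 * len(pep)]
        assert a.strand == "+"
        assert not detect_ptc(a)

    def test_reverse_strand_gene_recovered(self):
        rng = _rng(2)
        cds = _random_cds(100, rng)
        pep = translate_cds(cds)[:-1]
        region = _random_dna(300, rng) + _revcomp(cds) + _random_dna(300, rng)
        a = spliced_align(pep, region)
        assert a.strand == "-"
        assert a.inferred_cds == cds[:3 * len(pep)]
        # exon intervals address the forward strand of the region
        s, e = a.exon_intervals[0]
        assert region[s:e] == _revcomp(a.inferred_cds)

    def test_unrelated_sequence_reports_zero_coverage(self):
        rng = _rng(3)
        pep = translate_cds(_random_cds(150, rng))[:-1]
        a = spliced_align(pep, _random_dna(2000, rng))
        assert a.empty and a.aligned_protein_coverage == 0.0

    def test_planted_deletion_shortens_inferred_cds(self):
        rng = _rng(4)
        cds = _random_cds(150, rng)
        pep = translate_cds(cds)[:-1]
        lesioned = cds[:210] + cds[240:]   # 30 bp in-frame deletion
        region = _random_dna(200, rng) + lesioned + _random_dna(200, rng)
        a = spliced_align(pep, region)
        assert len(a.inferred_cds) == 3 * len(pep) - 30
        deficit = 3 * len(pep) - len(a.inferred_cds)
        assert deficit == 30

    def test_intron_bridged_by_long_gap_state(self):
        rng = _rng(5)
        cds = _random_cds(150, rng)
        pep = translate_cds(cds)[:-1]
        intron = "GT" + _random_dna(116, rng) + "AG"
        genomic = cds[:201] + intron + cds[201:]
        region = _random_dna(150, rng) + genomic + _random_dna(150, rng)
        a = spliced_align(pep, region)
        assert a.inferred_cds == cds[:3 * len(pep)]
        assert len(a.exon_intervals) == 2
        kinds = [k for k, _ in a.chunks]
        assert "intron" in kinds

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            spliced_align("MKV", "ACGT" * 100)


class TestDetectPtc:
    def _aln(self, codons):
        return SplicedAlignment(og_id="x", score=1, strand="+",
                                chunks=[("codon", c) for c in codons],
                                inferred_cds="".join(codons),
                                exon_intervals=[(0, 3 * len(codons))],
                                aligned_protein_coverage=1.0)

    def test_internal_stop_detected(self):
        codons = ["ATG", "GGT", "TAG", "CCC", "AAA"]
        assert detect_ptc(self._aln(codons))

    def test_terminal_stop_not_a_ptc(self):
        assert not detect_ptc(self._aln(["ATG", "GGT", "CCC", "TGA"]))

    def test_planted_nonsense_found_in_situ(self):
        rng = _rng(6)
        cds = _random_cds(120, rng)
        s = list(cds)
        s[3 * 40:3 * 40 + 3] = "TAA"
        lesioned = "".join(s)
        region = _random_dna(100, rng) + lesioned + _random_dna(100, rng)
        pep = translate_cds(cds)[:-1]
        a = spliced_align(pep, region)
        assert detect_ptc(a)
        stops = [i for i, (k, p) in enumerate(a.chunks)
                 if k == "codon" and p in ("TAA", "TAG", "TGA")]
        assert a.chunks[stops[0]][1] == "TAA"


class TestCodonAlign:
    def test_identical_sequences_all_paired(self):
        cds = _random_cds(50, _rng(7))
        pairs = codon_align(cds, cds)
        assert len(pairs) == 50
        assert all(not p.frameshifted and p.codon_a == p.codon_b for p in pairs)

    def test_single_synonymous_change(self):
        a = "ATGGGTCATTAA"
        b = "ATGGGCCATTAA"   # GGT -> GGC, same amino acid
        pairs = codon_align(a, b)
        diff = [p for p in pairs if p.codon_a != p.codon_b]
        assert len(diff) == 1 and not diff[0].frameshifted
        assert (diff[0].codon_a, diff[0].codon_b) == ("GGT", "GGC")

    def test_one_bp_deletion_flags_downstream_codons(self):
        cds = _random_cds(60, _rng(8))
        mutated = cds[:90] + cds[91:]     # 1-bp deletion mid-gene
        pairs = codon_align(cds, mutated)
        flags = [p.frameshifted for p in pairs]
        assert not any(flags[:25])
        assert all(flags[31:])

    def test_too_short_to_translate(self):
        with pytest.raises(ValueError):
            codon_align("AT", "ATGAAA")


# ---------------------------------------------------------------------------
# NG86 oracle (independent implementation: its own code table, permutation
# enumeration written from scratch)
# ---------------------------------------------------------------------------

_TCAG = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {a + b + c: _AA64[16 * i + 4 * j + k]
               for i, a in enumerate(_TCAG)
               for j, b in enumerate(_TCAG)
               for k, c in enumerate(_TCAG)}


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        s = v = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if ORACLE_CODE[alt] == "*":
                continue
            v += 1
            s += ORACLE_CODE[alt] == ORACLE_CODE[codon]
        if v:
            syn += s / v
    return syn, 3.0 - syn


def oracle_diffs(c1, c2):
    pos = [k for k in range(3) if c1[k] != c2[k]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(pos):
        cur, sd, nd, blocked = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            blocked = blocked or ORACLE_CODE[nxt] == "*"
            if ORACLE_CODE[nxt] == ORACLE_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    ok = [(s, n) for s, n, b in paths if not b] or \
         [(s, n) for s, n, _ in paths]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


def oracle_pn_ps(codon_pairs):
    S = N = Sd = Nd = 0.0
    for a, b in codon_pairs:
        sa, na = oracle_sites(a)
        sb, nb = oracle_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_diffs(a, b)
        Sd += sd
        Nd += nd
    return Nd / N, Sd / S


def random_codon_alignment(rng, n_codons=30, mut=0.15):
    sense = [c for c, aa in ORACLE_CODE.items() if aa != "*"]
    pairs = []
    while len(pairs) < n_codons:
        a = sense[rng.integers(len(sense))]
        b = list(a)
        for k in range(3):
            if rng.random() < mut:
                b[k] = "ACGT"[rng.integers(4)]
        b = "".join(b)
        if ORACLE_CODE[b] == "*":
            continue
        pairs.append((a, b))
    return pairs


class TestDnDs:
    def test_identical_sequences_have_no_valid_omega(self):
        pairs = [CodonPair(c, c, False) for c, _ in
                 random_codon_alignment(_rng(9), mut=0.0)]
        r = dnds(pairs)
        assert r.dn == pytest.approx(0.0) and r.ds == pytest.approx(0.0)
        assert not r.omega_valid

    def test_purely_nonsynonymous_alignment_is_invalid(self):
        # AAA(K)->GAA(E) etc: first-position changes, all nonsynonymous
        pairs = [CodonPair("AAA", "GAA", False), CodonPair("TTT", "CTT", False),
                 CodonPair("ATG", "CTG", False)] * 5
        r = dnds(pairs)
        assert r.ds == pytest.approx(0.0) and not r.omega_valid
        assert r.dn > 0

    def test_frameshifted_and_stop_codons_excluded(self):
        pairs = [CodonPair("AAA", "AAA", False),
                 CodonPair("AAA", "GGG", True),       # frameshifted: ignored
                 CodonPair("TAA", "TAA", False)]      # stop pair: ignored
        assert dnds(pairs).n_codons == 1

    def test_saturated_proportions_flagged(self):
        pairs = [CodonPair("AAA", "GGC", False), CodonPair("TTA", "GCG", False),
                 CodonPair("ATT", "CGG", False)] * 10
        r = dnds(pairs)
        assert r.saturated and not r.omega_valid

    def test_matches_pathway_enumeration_oracle(self):
        rng = _rng(10)
        for _ in range(50):
            pairs = random_codon_alignment(rng)
            r = dnds([CodonPair(a, b, False) for a, b in pairs])
            pn, ps = oracle_pn_ps(pairs)
            assert r.pn == pytest.approx(pn, abs=1e-9)
            assert r.ps == pytest.approx(ps, abs=1e-9)


# ---------------------------------------------------------------------------
# cohort recovery on the synthetic dataset
# ---------------------------------------------------------------------------

class TestCohortRecovery:
    def test_conserved_genes_look_conserved(self, dataset, characterized):
        pools = characterized.pipe.control_pools
        for sub in ("BhD", "BhS"):
            reports = pools[sub]
            assert all(not r.has_ptc for r in reports)
            deficits = [abs(r.length_deficit_bp) for r in reports]
            assert float(np.mean(deficits)) < 10.0
            omegas = [r.omega for r in reports if r.omega_valid]
            assert abs(float(np.mean(omegas))
                       - dataset.cfg.conserved_omega) < 0.1

    def test_relaxed_omega_contrast_recovered(self, dataset, characterized):
        s = characterized.summary
        assert s["pseudogenes"]["mean_omega"] > \
            s["control_mean"]["mean_omega"]
        assert abs(s["pseudogenes"]["mean_omega"]
                   - dataset.cfg.pseudogene_omega) < 0.1

    def test_ptc_flag_is_planted_nonsense_indicator(self, dataset,
                                                    characterized):
        """For remnants without deletions, has_ptc mirrors the planted
        nonsense lesions exactly."""
        truth = dataset.truth
        checked = 0
        for r in characterized.pipe.reports:
            pg = truth.pseudogenes.get(
                truth.pseudogene_by_og.get(r.og_id, ""), None)
            if pg is None or pg.deletion_spans or not r.aligned:
                continue
            checked += 1
            assert r.has_ptc == bool(pg.nonsense_codons), r.og_id
        assert checked >= 10

    def test_silenced_remnants_nonexpressed_everywhere(self, dataset,
                                                       characterized):
        truth = dataset.truth
        seen = 0
        for r in characterized.pipe.reports:
            pg = truth.pseudogenes.get(r.gene_id)
            if pg is None or not pg.silenced or not r.tpm_per_tissue:
                continue
            seen += 1
            assert all(r.nonexpressed_per_tissue.values())
        assert seen >= 5


# ---------------------------------------------------------------------------
# resampling control
# ---------------------------------------------------------------------------

def _report(deficit, omega=0.3, ptc=False):
    return PseudogeneReport(og_id="x", gene_id="x", alignment_bp=300,
                            diploid_cds_bp=300, length_deficit_bp=deficit,
                            has_ptc=ptc, omega=omega, omega_valid=True)


class TestControlTrials:
    def _pools(self, rng, n=60):
        return ([_report(float(rng.normal(0, 5))) for _ in range(n)],
                [_report(float(rng.normal(0, 5))) for _ in range(n)])

    def test_deterministic_for_fixed_seed(self):
        d, s = self._pools(_rng(11))
        a = control_trials(d, s, n_trials=20, per_trial_d=10, per_trial_s=10,
                           seed=5)
        b = control_trials(d, s, n_trials=20, per_trial_d=10, per_trial_s=10,
                           seed=5)
        assert a.trials.equals(b.trials)

    def test_extreme_observation_hits_p_floor(self):
        d, s = self._pools(_rng(12))
        c = control_trials(d, s, n_trials=1000, per_trial_d=10, per_trial_s=10,
                           seed=1)
        p = c.empirical_p(1e9, "mean_length_deficit", "greater")
        assert p == pytest.approx(1 / 1001)

    def test_single_trial_two_point_support(self):
        d, s = self._pools(_rng(13), n=12)
        c = control_trials(d, s, n_trials=1, per_trial_d=12, per_trial_s=12,
                           seed=1)
        obs = float(c.trials["mean_length_deficit"].iloc[0])
        assert c.empirical_p(obs, "mean_length_deficit") in (1.0,)
        assert c.empirical_p(obs + 1e9, "mean_length_deficit") == 0.5

    def test_pool_too_small_rejected(self):
        d, s = self._pools(_rng(14), n=5)
        with pytest.raises(ValueError):
            control_trials(d, s, per_trial_d=10, per_trial_s=10)

    def test_pvalues_superuniform_under_null(self):
        """Observed statistics drawn from the same pool should give p-values
        with P(p <= a) <= a (up to simulation error)."""
        rng = _rng(15)
        d, s = self._pools(rng, n=80)
        hits = 0
        reps = 200
        for i in range(reps):
            c = control_trials(d, s, n_trials=49, per_trial_d=10,
                               per_trial_s=10, seed=1000 + i)
            pick = rng.choice(80, size=20, replace=False)
            obs = float(np.mean([d[j].length_deficit_bp for j in pick[:10]]
                                + [s[j].length_deficit_bp for j in pick[10:]]))
            hits += c.empirical_p(obs, "mean_length_deficit") <= 0.1
        assert hits / reps <= 0.16


class TestNonexpressionEnrichment:
    def test_matches_exact_fraction_tail(self):
        n, k, p = 100, 100, Fraction(1, 10)
        tail = sum(comb(n, j) * p ** j * (1 - p) ** (n - j)
                   for j in range(k, n + 1))
        got = nonexpression_enrichment(k, n, 0.1)
        assert got == pytest.approx(float(tail), rel=1e-10)
        n, k = 50, 11
        tail = sum(comb(n, j) * p ** j * (1 - p) ** (n - j)
                   for j in range(k, n + 1))
        assert nonexpression_enrichment(11, 50, 0.1) == \
            pytest.approx(float(tail), rel=1e-10)

    def test_zero_nonexpressed_gives_p_one(self):
        assert nonexpression_enrichment(0, 200, 0.1) == pytest.approx(1.0)

    def test_observed_at_expectation_not_significant(self):
        p = nonexpression_enrichment(50, 500, 0.1)
        assert 0.4 < p < 0.7

    def test_degenerate_expected_frequencies(self):
        assert nonexpression_enrichment(0, 10, 0.0) == 1.0
        assert nonexpression_enrichment(3, 10, 0.0) == 0.0
        assert nonexpression_enrichment(10, 10, 1.0) == 1.0
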
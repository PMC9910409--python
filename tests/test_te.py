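"""TE composition, subgenome specificity, gene-TE proximity, K2P dating."""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pytest

from diploidizer.io_formats import GeneModel, LTRPair, TECopy
from diploidizer.te_analysis import (DEFAULT_SUBSTITUTION_RATE,
                                     K2PSaturationError, classify_specificity,
                                     composition_summary, date_ltr_pairs,
                                     family_age_profile, gene_te_overlap,
                                     gypsy_copia_ratios, insertion_time, k2p,
                                     specificity_paired_test)


def te(copy_id, family="f", klass="RLG", unit="BhD", chrom="BhD1",
       start=0, end=100, strand="+"):
    return TECopy(copy_id, family, klass, unit, chrom, start, end, strand)


class TestComposition:
    def test_gypsy_copia_ratio_arithmetic(self):
        copies = [te(f"g{i}", "fg", "RLG", end=200) for i in range(13)] + \
                 [te(f"c{i}", "fc", "RLC", end=100) for i in range(10)]
        ratios = gypsy_copia_ratios(composition_summary(copies))
        assert ratios.copy_ratio.iloc[0] == pytest.approx(1.3)
        assert ratios.mean_length_ratio.iloc[0] == pytest.approx(2.0)

    def test_empty_input_gives_empty_summary(self):
        assert composition_summary([]).empty

    def test_planted_family_bp_totals_recovered(self, dataset, pipeline):
        tes = pipeline.te_copies
        by_fam = defaultdict(int)
        for t in tes:
            by_fam[t.family_id] += t.length_bp
        assert by_fam == dataset.truth.te_family_bp


class TestSpecificity:
    def test_fully_one_sided_family_is_specific(self):
        copies = [te(f"c{i}", "fam", unit="BhD") for i in range(10)]
        fams, pct, _ = classify_specificity(copies, "BhD", "BhS")
        assert fams[0].specificity == "D-specific"
        assert pct == 100.0

    def test_four_copies_ineligible(self):
        copies = [te(f"c{i}", "fam", unit="BhD") for i in range(4)]
        fams, pct, _ = classify_specificity(copies, "BhD", "BhS")
        assert fams[0].specificity == "ineligible" and pct == 0.0

    def test_exact_ninety_percent_boundary_inclusive(self):
        copies = [te(f"c{i}", "fam", unit="BhS", chrom="BhS1")
                  for i in range(9)] + [te("c9", "fam", unit="BhD")]
        fams, _, _ = classify_specificity(copies, "BhD", "BhS")
        assert fams[0].specificity == "S-specific"

    def test_agrees_with_bruteforce_recount_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for trial in range(100):
            copies = []
            n_fam = rng.integers(2, 8)
            for f in range(n_fam):
                for c in range(rng.integers(1, 15)):
                    u = "BhD" if rng.random() < rng.uniform(0, 1) else "BhS"
                    copies.append(te(f"t{trial}f{f}c{c}", f"fam{f}", unit=u,
                                     chrom=f"{u}{1 + c % 2}"))
            fams, pct, _ = classify_specificity(copies, "BhD", "BhS")
            # brute-force recount
            spec_fams = set()
            for f in {t.family_id for t in copies}:
                mine = [t for t in copies if t.family_id == f]
                nd = sum(t.unit_id == "BhD" for t in mine)
                if len(mine) >= 5 and max(nd, len(mine) - nd) / len(mine) >= 0.9:
                    spec_fams.add(f)
            expect = 100.0 * sum(t.family_id in spec_fams for t in copies) \
                / len(copies)
            assert pct == pytest.approx(expect)
            got = {s.family_id for s in fams if s.specificity.endswith("-specific")}
            assert got == spec_fams

    def test_planted_specificity_recovered(self, dataset, pipeline):
        fams, _, _ = classify_specificity(pipeline.te_copies, "BhD", "BhS")
        planted = dataset.truth.te_families
        for s in fams:
            if planted[s.family_id] in ("D-specific", "S-specific"):
                assert s.specificity == planted[s.family_id]
            elif planted[s.family_id] == "ineligible":
                assert s.specificity == "ineligible"


class TestPairedTest:
    def test_identical_vectors(self):
        r = specificity_paired_test([1.0, 2, 3], [1.0, 2, 3])
        assert r.t_statistic == 0.0 and r.p_value == 1.0 and r.degenerate

    def test_constant_offset_degenerate(self):
        r = specificity_paired_test([2.0, 3, 4], [1.0, 2, 3])
        assert r.degenerate and r.p_value == 0.0

    def test_matches_r_reference(self):
        # R: t.test(a, b, paired=TRUE), %.17g
        a = [12.1, 10.3, 14.7, 9.2, 11.8, 13.4, 10.9]
        b = [16.0, 11.2, 13.9, 12.5, 13.1, 15.8, 12.2]
        r = specificity_paired_test(a, b)
        assert r.t_statistic == pytest.approx(-2.9327307424534665, abs=1e-10)
        assert r.p_value == pytest.approx(0.026193912331118382, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            specificity_paired_test([1.0], [2.0])


class TestGeneTeOverlap:
    def _genes(self):
        return [GeneModel("g1", "BhD", "BhD1", 1000, 3000, "+",
                          exons=[(1000, 1400), (2500, 3000)]),
                GeneModel("g2", "BhD", "BhD1", 10_000, 12_000, "-",
                          exons=[(10_000, 12_000)])]

    def test_intronic_same_strand_counts_gene_not_exon(self):
        tes = [te("t1", start=1500, end=1900, strand="+")]
        r = gene_te_overlap(self._genes(), tes)
        assert r.pct_genes_overlapping_te == pytest.approx(50.0)
        assert r.pct_exons_overlapping_te == 0.0
        assert r.mean_te_gene_distance_bp == 0.0

    def test_opposite_strand_overlap_ignored_but_distance_zero(self):
        tes = [te("t1", start=1500, end=1900, strand="-")]
        r = gene_te_overlap(self._genes(), tes)
        assert r.pct_genes_overlapping_te == 0.0
        assert r.mean_te_gene_distance_bp == 0.0

    def test_sparse_fixture_matches_hand_computation(self):
        tes = [te("a", start=1200, end=1300, strand="+"),   # exon of g1
               te("b", start=5000, end=6000, strand="+"),   # between genes
               te("c", start=11_000, end=11_500, strand="+")]  # in g2, wrong strand
        r = gene_te_overlap(self._genes(), tes)
        assert r.pct_genes_overlapping_te == pytest.approx(50.0)
        assert r.pct_exons_overlapping_te == pytest.approx(100 / 3)
        # distances: a=0, b=min(5000-3000, 10000-6000)=2000, c=0
        assert r.mean_te_gene_distance_bp == pytest.approx(2000 / 3)

    def test_matches_bruteforce_scan_on_random_fixture(self):
        rng = np.random.default_rng(8)
        genes = [GeneModel(f"g{i}", "BhD", "BhD1", int(s), int(s) + 500,
                           "+-"[int(rng.integers(2))])
                 for i, s in enumerate(sorted(rng.choice(50_000, 20,
                                                         replace=False)))]
        tes = [te(f"t{i}", start=int(p), end=int(p) + 200,
                  strand="+-"[int(rng.integers(2))])
               for i, p in enumerate(rng.integers(0, 50_000, 30))]
        r = gene_te_overlap(genes, tes)
        hit = sum(any(t.strand == g.strand and t.start < g.end
                      and g.start < t.end for t in tes) for g in genes)
        assert r.pct_genes_overlapping_te == pytest.approx(100 * hit / 20)
        dists = [min(max(0, max(g.start - t.end, t.start - g.end))
                     for g in genes) for t in tes]
        assert r.mean_te_gene_distance_bp == pytest.approx(float(np.mean(dists)))


class TestK2P:
    def test_identical_ltrs_have_zero_divergence(self):
        seq = "ACGT" * 250
        d = k2p(LTRPair("e", "u", seq, seq))
        assert (d.p_transitions, d.q_transversions, d.k2p_divergence) == (0, 0, 0)

    def test_closed_form_evaluation(self):
        # 100 sites, 2 transitions (A<->G), 1 transversion (A<->T)
        a = list("ACGT" * 25)
        b = a.copy()
        b[0] = "G"; b[4] = "G"; b[8] = "T"
        d = k2p(LTRPair("e", "u", "".join(a), "".join(b)))
        assert d.p_transitions == pytest.approx(0.02)
        assert d.q_transversions == pytest.approx(0.01)
        assert d.k2p_divergence == pytest.approx(
            -0.5 * math.log(0.95 * math.sqrt(0.98)))

    def test_n_columns_removed_before_counting(self):
        a = "AAAAACGTCGTCGT" + "ACGT" * 20
        b = "NAAAACGTCGTCGT" + "ACGT" * 20
        d = k2p(LTRPair("e", "u", a, b))
        assert d.n_sites == len(a) - 1 and d.k2p_divergence == 0.0

    def test_p_distance_limit(self):
        """D/(P+Q) -> 1 as P,Q -> 0 (within 1% at 1e-4)."""
        n = 40_000
        a = list("ACGT" * (n // 4))
        b = a.copy()
        b[0] = "G"; b[5] = "T"; b[9] = "C"; b[13] = "A"
        d = k2p(LTRPair("e", "u", "".join(a), "".join(b)))
        ratio = d.k2p_divergence / (d.p_transitions + d.q_transversions)
        assert abs(ratio - 1.0) < 0.01

    def test_saturation_is_an_error(self):
        a = "A" * 400
        b = "G" * 400
        with pytest.raises(K2PSaturationError):
            k2p(LTRPair("e", "u", a, b))


class TestInsertionTime:
    def test_formula_at_the_reference_point(self):
        assert insertion_time(0.0364, 1.3e-8) == pytest.approx(1.4e6, rel=1e-12)

    def test_zero_divergence_zero_age_and_linearity(self):
        assert insertion_time(0.0) == 0.0
        assert insertion_time(0.02) * 2 == pytest.approx(insertion_time(0.04))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            insertion_time(-0.1)
        with pytest.raises(ValueError):
            insertion_time(0.1, rate=0.0)


class TestAgeRecovery:
    def test_planted_ages_recovered_within_ten_percent(self, dataset):
        from diploidizer.io_formats import read_ltr_pairs
        pairs = read_ltr_pairs(dataset.paths["ltr"])
        dated, excluded = date_ltr_pairs(pairs)
        assert not excluded
        ages = defaultdict(list)
        for d in dated:
            ages[dataset.truth.ltr_ages[d.element_id]].append(
                d.insertion_time_years)
        for planted, estimates in ages.items():
            assert len(estimates) == 100
            assert abs(float(np.mean(estimates)) - planted) <= 0.1 * planted

    def test_family_age_profile(self):
        from diploidizer.te_analysis import DatedLTR
        ltrs = [DatedLTR("a", "BhD", "f1", 0, 0, 0, 1e5),
                DatedLTR("b", "BhD", "f1", 0, 0, 0, 9e5),
                DatedLTR("c", "BhS", "f2", 0, 0, 0, 2e6)]
        prof = family_age_profile(ltrs, min_intact=2, age_threshold_years=1.4e6)
        assert prof.lifespans == {"f1": pytest.approx(8e5)}
        assert "f2" not in prof.lifespans       # single member: excluded
        assert prof.young_fraction_per_unit["BhD"] == 1.0
        assert prof.young_fraction_per_unit["BhS"] == 0.0
        assert prof.young_fraction == pytest.approx(2 / 3)
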
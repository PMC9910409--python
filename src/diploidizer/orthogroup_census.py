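"""Presence/absence census of orthogroups across genome units, and the
chi-square tests for differential and biased gene loss.

The census universe is the set of orthogroups with at least one member in
some genome unit; each orthogroup is assigned exactly one category:

* ``complete`` — every declared unit has at least one member,
* ``single_missing(<unit>)`` — exactly one unit has none (the gene-loss
  signal of interest: a gene conserved everywhere else),
* ``multi_missing`` — two or more units lack members (tallied, not analyzed
  further).

Both tests are 2x2 Pearson chi-squares with Yates continuity correction
(applied unconditionally; an uncorrected variant is behind a flag).  The
differential-loss test compares missing/retained counts between two genomes;
the biased-loss test compares lost counts between the two subgenomes with
each subgenome's total gene count defining the null.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Orthogroup


@dataclass
class PresencePattern:
    og_id: str
    absent_units: frozenset[str]
    category: str   # "complete" | "single_missing:<unit>" | "multi_missing"


@dataclass
class LossTestResult:
    statistic: float
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    yates: bool
    low_expected: bool      # some expected cell < 1


def census(orthogroups: Sequence[Orthogroup], unit_ids: Sequence[str],
           ) -> tuple[list[PresencePattern], Counter]:
    """Classify every orthogroup; counts per category are the UpSet-style bars."""
    if not unit_ids:
        raise ValueError("empty unit list")
    patterns: list[PresencePattern] = []
    counts: Counter = Counter()
    for og in orthogroups:
        absent = frozenset(og.absent_units(unit_ids))
        if not absent:
            cat = "complete"
        elif len(absent) == 1:
            cat = f"single_missing:{next(iter(absent))}"
        else:
            cat = "multi_missing"
        patterns.append(PresencePattern(og.og_id, absent, cat))
        counts[cat] += 1
    return patterns, counts


def single_missing(patterns: Iterable[PresencePattern], unit_id: str,
                   ) -> list[PresencePattern]:
    return [p for p in patterns if p.category == f"single_missing:{unit_id}"]


def _chi2_2x2(table: np.ndarray, yates: bool) -> LossTestResult:
    chi2, p, _, expected = stats.chi2_contingency(table, correction=yates)
    return LossTestResult(statistic=float(chi2), p_value=float(p),
                          observed=table, expected=expected, yates=yates,
                          low_expected=bool((expected < 1).any()))


def loss_rate_test(missing_a: int, total_genes_a: int,
                   missing_b: int, total_genes_b: int,
                   yates: bool = True) -> LossTestResult:
    """Is the missing-gene rate different between two genomes?

    2x2 table of missing vs retained counts, chi-square with Yates
    continuity correction.
    """
    if missing_a > total_genes_a or missing_b > total_genes_b:
        raise ValueError("missing exceeds total")
    if total_genes_a <= 0 or total_genes_b <= 0:
        raise ValueError("totals must be positive")
    table = np.array([[missing_a, total_genes_a - missing_a],
                      [missing_b, total_genes_b - missing_b]])
    return _chi2_2x2(table, yates)


def biased_loss_test(lost_d: int, lost_s: int, total_d: int, total_s: int,
                     yates: bool = True) -> LossTestResult:
    """Is gene loss biased between the two subgenomes beyond what their total
    gene counts predict?  Same 2x2 Yates chi-square, with subgenome totals
    defining the null."""
    return loss_rate_test(lost_d, total_d, lost_s, total_s, yates=yates)


def census_table(patterns: Sequence[PresencePattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"og_id": p.og_id, "category": p.category,
          "absent_units": ",".join(sorted(p.absent_units))} for p in patterns])
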
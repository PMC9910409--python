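"""Homeolog expression bias and subgenome expression dominance.

Two complementary views of whether one subgenome out-expresses the other:

* **homeolog bias** — for each 1:1 homeolog pair, which copy has the higher
  TPM?  Pairs where both copies have TPM < 1.0 are filtered as noise, exact
  ties are dropped, and the count of D-favoring pairs is tested against 0.5
  with a two-sided exact binomial test at a Bonferroni-corrected alpha
  (0.05 / number of tissues = 0.0125 for the standard 4-tissue design).

* **subgenome dominance** — on *raw counts*: the share of all reads coming
  from D-subgenome genes, against a null given by the D share of total
  primary-transcriptome base pairs (more transcript bp attract more reads
  even without dominance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

log = logging.getLogger("diploidizer")

DEFAULT_ALPHA = 0.0125   # 0.05 Bonferroni-corrected for 4 tissues
TPM_NOISE_FLOOR = 1.0


def counts_to_tpm(matrix: ExpressionMatrix,
                  transcript_lengths: Mapping[str, int] | pd.Series,
                  ) -> ExpressionMatrix:
    """TPM_g = 1e6 * (count_g / len_g) / sum_h (count_h / len_h), per tissue.

    Every gene needs a positive length; an all-zero tissue yields all-zero
    TPMs with a warning rather than a division error.
    """
    lengths = pd.Series(transcript_lengths, dtype=float)
    missing = matrix.counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no transcript length for genes: {list(missing[:10])}")
    lengths = lengths.reindex(matrix.counts.index)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rate = matrix.counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        log.warning("tissue(s) %s have zero total counts; TPM set to 0",
                    list(denom.index[zero]))
        denom = denom.mask(zero, 1.0)
    tpm = rate.div(denom, axis=1) * 1e6
    return ExpressionMatrix(counts=matrix.counts, tpm=tpm)


def bias_pvalue(n_favor_d: int, n_used: int, alternative: str = "two-sided",
                ) -> float:
    """Exact binomial p-value for the D-favoring count against 0.5."""
    return float(stats.binomtest(n_favor_d, n_used, 0.5,
                                 alternative=alternative).pvalue)


@dataclass
class BiasResult:
    tissue: str
    n_pairs_used: int
    n_favor_d: int
    n_ties_dropped: int
    n_filtered: int
    fraction_favoring_d: float
    p_value: float
    alpha: float
    significant: bool
    undefined: bool = False


def homeolog_bias(pairs: pd.DataFrame, tpm: pd.DataFrame, tissue: str,
                  alpha: float = DEFAULT_ALPHA,
                  alternative: str = "two-sided") -> BiasResult:
    """Which homeolog wins, pair by pair, in one tissue?

    ``pairs`` needs columns ``d_gene`` and ``s_gene`` (1:1 homeologs).
    """
    d = tpm.loc[pairs["d_gene"], tissue].to_numpy()
    s = tpm.loc[pairs["s_gene"], tissue].to_numpy()
    noisy = (d < TPM_NOISE_FLOOR) & (s < TPM_NOISE_FLOOR)
    d, s = d[~noisy], s[~noisy]
    ties = d == s
    n_favor_d = int((d[~ties] > s[~ties]).sum())
    n_used = int((~ties).sum())
    if n_used == 0:
        return BiasResult(tissue=tissue, n_pairs_used=0, n_favor_d=0,
                          n_ties_dropped=int(ties.sum()),
                          n_filtered=int(noisy.sum()),
                          fraction_favoring_d=float("nan"), p_value=float("nan"),
                          alpha=alpha, significant=False, undefined=True)
    p = bias_pvalue(n_favor_d, n_used, alternative)
    return BiasResult(tissue=tissue, n_pairs_used=n_used, n_favor_d=n_favor_d,
                      n_ties_dropped=int(ties.sum()), n_filtered=int(noisy.sum()),
                      fraction_favoring_d=n_favor_d / n_used, p_value=p,
                      alpha=alpha, significant=p < alpha)


@dataclass
class DominanceResult:
    tissue: str
    observed_d_count_share: float
    expected_d_share: float
    deviation: float


def subgenome_dominance(matrix: ExpressionMatrix, gene_units: Mapping[str, str],
                        transcript_lengths: Mapping[str, int], tissue: str,
                        d_unit: str, s_unit: str) -> DominanceResult:
    """Observed share of raw counts from D genes vs the transcriptome-length
    null expectation."""
    counts = matrix.counts[tissue]
    units = pd.Series({g: gene_units.get(g, "") for g in counts.index})
    keep = units.isin([d_unit, s_unit])
    counts = counts[keep.to_numpy()]
    units = units[keep.to_numpy()]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"tissue {tissue!r} has zero total counts")
    observed = float(counts[(units == d_unit).to_numpy()].sum() / total)
    lengths = pd.Series({g: transcript_lengths[g] for g in counts.index},
                        dtype=float)
    expected = float(lengths[(units == d_unit).to_numpy()].sum() / lengths.sum())
    return DominanceResult(tissue=tissue, observed_d_count_share=observed,
                           expected_d_share=expected,
                           deviation=observed - expected)


def bias_table(pairs: pd.DataFrame, tpm: pd.DataFrame,
               tissues: Sequence[str], alpha: float = DEFAULT_ALPHA,
               ) -> pd.DataFrame:
    rows = [homeolog_bias(pairs, tpm, t, alpha=alpha).__dict__ for t in tissues]
    return pd.DataFrame(rows)
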
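"""Protein-to-genome spliced alignment.

A local (Smith-Waterman-style) dynamic program aligning a peptide against
both strands of a genomic region, codon-aware, with a two-tier gap model:

* ordinary affine indels (per-nucleotide in the genome, per-residue in the
  peptide),
* frameshift "codons" consuming 2 or 4 nt at a fixed penalty,
* a cheap long-gap *intron* state, rewarded when its boundaries carry the
  canonical GT..AG splice dinucleotides.

The traceback is kept as a list of chunks — ``codon`` (3 nt against one
residue), ``fs`` (2/4 nt frameshift), ``ins`` (genomic nt with no residue),
``del`` (residue with no genomic nt), ``intron`` — from which the inferred
coding sequence (everything but introns), the exon intervals, the codon
phase map, and the aligned-protein coverage all derive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BLOSUM = substitution_matrices.load("BLOSUM62")
AA_SCORE = np.zeros((24, 24), dtype=np.float32)
for _i, _a in enumerate(AA_ALPHABET):
    for _j, _b in enumerate(AA_ALPHABET):
        AA_SCORE[_i, _j] = _BLOSUM[_a][_b]

# codon (5x5x5 incl. N) -> amino-acid index; N-containing codons -> X
from .synthetic_data import CODON2AA  # the canonical code table

CODON_AA = np.full((5, 5, 5), _AA_INDEX["X"], dtype=np.int8)
for _cod, _aa in CODON2AA.items():
    i, j, k = (_NT_INDEX[c] for c in _cod)
    CODON_AA[i, j, k] = _AA_INDEX[_aa]

STOP_SET = {"TAA", "TAG", "TGA"}

# scoring constants
GO_NT, GE_NT = np.float32(-12.0), np.float32(-3.0)    # genomic short gaps
GO_AA, GE_AA = np.float32(-12.0), np.float32(-2.0)    # peptide gaps
FS_PEN = np.float32(-15.0)                            # 2/4-nt frameshift codon
INTRON_OPEN, INTRON_EXT = np.float32(-20.0), np.float32(-0.25)
SPLICE_BONUS = np.float32(6.0)
NEG = np.float32(-1e9)

SCORE_THRESHOLD_FRACTION = 0.25   # of the peptide's self-alignment score


def encode_dna(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8).astype(np.int8)


def encode_peptide(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, _AA_INDEX["X"]) for a in seq.upper()],
                    dtype=np.int8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=True, fastmath=False)
def _fill(dna, pep, aa_score, codon_aa):     # pragma: no cover - numba
    n, m = dna.shape[0], pep.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    J = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pIx = np.zeros((n + 1, m + 1), dtype=np.int8)
    pIy = np.zeros((n + 1, m + 1), dtype=np.int8)
    pJ = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[:, 0] = 0.0
    M[0, :] = 0.0
    best, bi, bj = np.float32(0.0), 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # --- match state: consume one residue against 3 (or 2/4) nt
            sc_best = np.float32(0.0)
            ptr = np.int8(0)
            if i >= 3:
                s = aa_score[codon_aa[dna[i - 3], dna[i - 2], dna[i - 1]],
                             pep[j - 1]]
                v = M[i - 3, j - 1] + s
                if v > sc_best:
                    sc_best, ptr = v, np.int8(1)
                v = Ix[i - 3, j - 1] + s
                if v > sc_best:
                    sc_best, ptr = v, np.int8(2)
                v = Iy[i - 3, j - 1] + s
                if v > sc_best:
                    sc_best, ptr = v, np.int8(3)
                acc = np.float32(0.0)
                if i >= 5 and dna[i - 5] == 0 and dna[i - 4] == 2:
                    acc = SPLICE_BONUS
                v = J[i - 3, j - 1] + s + acc
                if v > sc_best:
                    sc_best, ptr = v, np.int8(4)
            if i >= 2:
                v = M[i - 2, j - 1] + FS_PEN
                if v > sc_best:
                    sc_best, ptr = v, np.int8(5)
            if i >= 4:
                v = M[i - 4, j - 1] + FS_PEN
                if v > sc_best:
                    sc_best, ptr = v, np.int8(6)
            M[i, j] = sc_best
            pM[i, j] = ptr
            if sc_best > best:
                best, bi, bj = sc_best, i, j
            # --- short genomic insertion
            vo = M[i - 1, j] + GO_NT
            ve = Ix[i - 1, j] + GE_NT
            if vo >= ve:
                Ix[i, j] = vo
                pIx[i, j] = 0
            else:
                Ix[i, j] = ve
                pIx[i, j] = 1
            # --- peptide gap (deleted residues)
            vo = M[i, j - 1] + GO_AA
            ve = Iy[i, j - 1] + GE_AA
            if vo >= ve:
                Iy[i, j] = vo
                pIy[i, j] = 0
            else:
                Iy[i, j] = ve
                pIy[i, j] = 1
            # --- intron state (long cheap genomic gap, GT.. rewarded)
            don = np.float32(0.0)
            if dna[i - 1] == 2 and i < n and dna[i] == 3:
                don = SPLICE_BONUS
            vo = M[i - 1, j] + INTRON_OPEN + don
            ve = J[i - 1, j] + INTRON_EXT
            if vo >= ve:
                J[i, j] = vo
                pJ[i, j] = 0
            else:
                J[i, j] = ve
                pJ[i, j] = 1
    return M, pM, pIx, pIy, pJ, best, bi, bj


@dataclass
class RawAlignment:
    score: float
    chunks: list            # [(kind, payload)] forward order
    dna_start: int
    dna_end: int
    pep_start: int
    pep_end: int


def _traceback(dna_str: str, pM, pIx, pIy, pJ, bi: int, bj: int) -> RawAlignment:
    chunks: list[tuple[str, str]] = []
    i, j = bi, bj
    state = "M"
    while True:
        if state == "M":
            p = pM[i, j]
            if p == 0:
                break
            if p in (1, 2, 3, 4):
                chunks.append(("codon", dna_str[i - 3:i]))
                i, j = i - 3, j - 1
                state = {1: "M", 2: "Ix", 3: "Iy", 4: "J"}[int(p)]
            elif p == 5:
                chunks.append(("fs", dna_str[i - 2:i]))
                i, j = i - 2, j - 1
            else:
                chunks.append(("fs", dna_str[i - 4:i]))
                i, j = i - 4, j - 1
        elif state == "Ix":
            chunks.append(("ins", dna_str[i - 1:i]))
            state = "M" if pIx[i, j] == 0 else "Ix"
            i -= 1
        elif state == "Iy":
            chunks.append(("del", ""))
            state = "M" if pIy[i, j] == 0 else "Iy"
            j -= 1
        else:  # intron
            chunks.append(("intron", dna_str[i - 1:i]))
            state = "M" if pJ[i, j] == 0 else "J"
            i -= 1
    chunks.reverse()
    merged: list[tuple[str, str]] = []
    for kind, payload in chunks:
        if merged and kind in ("intron", "ins") and merged[-1][0] == kind:
            merged[-1] = (kind, merged[-1][1] + payload)
        else:
            merged.append((kind, payload))
    return RawAlignment(score=0.0, chunks=merged, dna_start=i, dna_end=bi,
                        pep_start=j, pep_end=bj)


def align_protein_to_dna(peptide: str, dna: str) -> RawAlignment:
    """Best local spliced alignment of ``peptide`` against one strand of ``dna``."""
    d = encode_dna(dna)
    p = encode_peptide(peptide)
    M, pM, pIx, pIy, pJ, best, bi, bj = _fill(d, p, AA_SCORE, CODON_AA)
    raw = _traceback(dna, pM, pIx, pIy, pJ, int(bi), int(bj))
    raw.score = float(best)
    return raw


def self_score(peptide: str) -> float:
    p = encode_peptide(peptide)
    return float(AA_SCORE[p, p].sum())
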
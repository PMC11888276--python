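"""Vocabulary ranking and motif enrichment.

Each trained model assigns a weight to every possible l-mer; ranking that
vocabulary and scanning the top fraction for transcription-factor motifs
(JASPAR-style PFMs, log-odds vs a uniform background) shows which binding
motifs drive each cell-class model.  Counts per motif across models are
converted to row-wise z-scores to highlight class-specific enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gkm import KmerWeightTable, decode_codes, sliding_codes
from .io import MotifPFM


@dataclass
class VocabularyEntry:
    kmer: str
    score: float
    rank: int  # 1 = highest


@dataclass
class RankedVocabulary:
    """The full (or truncated) l-mer vocabulary sorted by descending weight.

    Kept as packed code / score arrays; decode to strings only on demand —
    the full l=11 vocabulary has 4^11 = 4,194,304 entries.
    """

    word_length: int
    codes: np.ndarray   # packed l-mer codes in rank order
    scores: np.ndarray  # non-increasing
    total_size: int     # size of the vocabulary this ranking was drawn from

    def __len__(self) -> int:
        return len(self.codes)

    def kmers(self) -> list[str]:
        return decode_codes(self.codes, self.word_length)

    def entries(self) -> list[VocabularyEntry]:
        return [VocabularyEntry(kmer, float(s), i + 1)
                for i, (kmer, s) in enumerate(zip(self.kmers(), self.scores))]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tkmer\tscore\n")
            for i, (kmer, s) in enumerate(zip(self.kmers(), self.scores), start=1):
                fh.write(f"{i}\t{kmer}\t{s:.8g}\n")


def rank_vocabulary(table: KmerWeightTable) -> RankedVocabulary:
    """Sort all l-mers by descending weight; ties break lexicographically.

    Lexicographic kmer order coincides with ascending packed-code order.
    """
    codes = np.arange(len(table.weights), dtype=np.uint32)
    order = np.lexsort((codes, -table.weights))
    return RankedVocabulary(word_length=table.word_length,
                            codes=codes[order],
                            scores=table.weights[order],
                            total_size=len(table.weights))


def top_fraction(vocab: RankedVocabulary, fraction: float = 0.01) -> RankedVocabulary:
    """First floor(fraction * N) entries of the ranked vocabulary."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = int(np.floor(fraction * vocab.total_size))
    if n == 0:
        warnings.warn(f"top fraction {fraction} of {vocab.total_size} k-mers "
                      "is empty", stacklevel=2)
    return RankedVocabulary(vocab.word_length, vocab.codes[:n],
                            vocab.scores[:n], vocab.total_size)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _window_scores(seq_digits: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds of a PWM (4 x M log-odds) over all windows of a digit array."""
    m = lo.shape[1]
    n = len(seq_digits) - m + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(m):
        scores += lo[seq_digits[j : j + n], j]
    return scores


def match_pwm_to_kmer(pfm: MotifPFM, kmer: str,
                      threshold_frac: float = 0.8) -> list[tuple[int, str, float]]:
    """All PWM hits within a k-mer (or a short k-mer within a longer PWM).

    A hit is a placement whose log-odds score (uniform background,
    pseudocount ``pfm.pseudocount_frac`` of the column sum) reaches
    ``threshold_frac`` of the maximum attainable score of the scored window.
    Both strands are scanned.  Returns (offset, strand, score) with the
    offset on the forward k-mer.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    from .gkm import encode_sequence

    lo = pfm.log_odds()
    digits = encode_sequence(kmer)
    hits: list[tuple[int, str, float]] = []
    if len(kmer) >= pfm.length:
        threshold = threshold_frac * pfm.max_score()
        fwd = _window_scores(digits, lo)
        rev = _window_scores(digits, lo[::-1, ::-1])  # PWM on the minus strand
        for off in range(len(fwd)):
            if fwd[off] >= threshold:
                hits.append((off, "+", float(fwd[off])))
            if rev[off] >= threshold:
                hits.append((off, "-", float(rev[off])))
    else:
        # short word inside a longer PWM: compare against each sub-window of
        # the PWM, thresholding on that sub-window's own maximum
        w = len(kmer)
        submax = lo.max(axis=0)
        for start in range(pfm.length - w + 1):
            sub = lo[:, start : start + w]
            threshold = threshold_frac * submax[start : start + w].sum()
            fwd = float(sub[digits, np.arange(w)].sum())
            rev = float(sub[::-1, ::-1][digits, np.arange(w)].sum())
            if fwd >= threshold:
                hits.append((0, "+", fwd))
            if rev >= threshold:
                hits.append((0, "-", rev))
    return hits


def _count_hits_batch(pfm: MotifPFM, kmer_digits: np.ndarray,
                      threshold_frac: float) -> int:
    """Total hit count of one PFM over a (N, l) matrix of k-mer digits."""
    n_kmers, l = kmer_digits.shape
    lo = pfm.log_odds()
    m = pfm.length
    total = 0
    if l >= m:
        threshold = threshold_frac * pfm.max_score()
        for mat in (lo, lo[::-1, ::-1]):
            for off in range(l - m + 1):
                scores = np.zeros(n_kmers)
                for j in range(m):
                    scores += mat[kmer_digits[:, off + j], j]
                total += int((scores >= threshold).sum())
    else:
        submax = lo.max(axis=0)
        for start in range(m - l + 1):
            threshold = threshold_frac * submax[start : start + l].sum()
            for mat in (lo, lo[::-1, ::-1]):
                sub = mat[:, start : start + l]
                scores = np.zeros(n_kmers)
                for j in range(l):
                    scores += sub[kmer_digits[:, j], j]
                total += int((scores >= threshold).sum())
    return total


def _vocab_digits(vocab: RankedVocabulary) -> np.ndarray:
    codes = vocab.codes.astype(np.uint64)
    l = vocab.word_length
    digits = np.empty((len(codes), l), dtype=np.uint8)
    for j in range(l):
        digits[:, l - 1 - j] = (codes >> np.uint64(2 * j)) & np.uint64(3)
    return digits


def count_motifs_in_top_vocab(top: RankedVocabulary, pfms: list[MotifPFM],
                              whitelist: set[str] | None = None,
                              threshold_frac: float = 0.8) -> pd.Series:
    """Total motif occurrences (hits, not k-mers) in a top vocabulary set.

    Motifs whose TF name is absent from a non-empty whitelist are dropped;
    an empty/None whitelist applies no filtering.
    """
    if not pfms:
        raise ValueError("no PFMs supplied")
    kept = [p for p in pfms
            if not whitelist or p.name.upper() in whitelist]
    digits = _vocab_digits(top)
    counts = {}
    for pfm in kept:
        counts[pfm.id] = (_count_hits_batch(pfm, digits, threshold_frac)
                          if len(top) else 0)
    return pd.Series(counts, name="count", dtype=int)


@dataclass
class MotifCountMatrix:
    """Motif-by-model hit counts and the per-motif (row-wise) z-scores."""

    counts: pd.DataFrame               # rows = motif ids, columns = models
    zscores: pd.DataFrame | None = None


def count_matrix(tops_by_model: dict[str, RankedVocabulary],
                 pfms: list[MotifPFM], whitelist: set[str] | None = None,
                 threshold_frac: float = 0.8) -> MotifCountMatrix:
    cols = {label: count_motifs_in_top_vocab(top, pfms, whitelist, threshold_frac)
            for label, top in tops_by_model.items()}
    return MotifCountMatrix(counts=pd.DataFrame(cols))


def motif_zscores(matrix: MotifCountMatrix) -> MotifCountMatrix:
    """Row-wise z-score of each motif's count across model columns.

    Sample standard deviation (ddof=1); constant rows get z = 0.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("z-scores need at least 2 model columns")
    values = counts.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    return MotifCountMatrix(counts=counts,
                            zscores=pd.DataFrame(z, index=counts.index,
                                                 columns=counts.columns))
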
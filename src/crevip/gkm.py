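"""Gapped k-mer SVM: kernel, training, prediction, cross-validation and the
complete l-mer weight table.

The gapped k-mer kernel between two sequences is the inner product of their
gapped k-mer count vectors: over all pairs of length-``l`` words (one from
each sequence) the pair contributes ``C(l - m, k)`` shared gapped k-mers,
where ``m`` is the Hamming distance between the words — the number of ways to
choose ``k`` informative positions among the ``l - m`` matching ones.  With
both-strand counting the second sequence contributes the words of both
strands, which makes every derived quantity invariant to reverse
complementation.  Models are one-vs-background soft-margin SVMs fitted on the
normalised kernel matrix; the full weight table scores every possible l-mer
with the trained decision function (minus the bias), which is the additive
engine behind deltaSVM variant scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import average_precision_score, auc, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import _kernel
from .io import DNA_ALPHABET

__all__ = [
    "GkmParams", "GkmModel", "KmerWeightTable", "CvResult",
    "gkm_pair_contribution", "gkm_kernel", "train_model", "predict_score",
    "predict_scores", "extract_kmer_weights", "cross_validate",
    "cross_class_score_matrix", "encode_sequence", "sliding_codes",
    "revcomp_codes", "decode_codes", "reverse_complement",
]

_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_ALPHABET):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T} to base codes 0..3; anything else raises."""
    arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in seq if c.upper() not in DNA_ALPHABET})
        raise ValueError(f"sequence contains non-ACGT characters {bad}")
    return arr


def sliding_codes(seq: str | np.ndarray, l: int) -> np.ndarray:
    """Packed codes of all sliding l-mers of ``seq`` (5' base in high bits)."""
    arr = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if len(arr) < l:
        raise ValueError(f"sequence of length {len(arr)} shorter than word length {l}")
    n = len(arr) - l + 1
    codes = np.zeros(n, dtype=np.uint32)
    for j in range(l):
        codes = (codes << np.uint32(2)) | arr[j : j + n].astype(np.uint32)
    return codes


def revcomp_codes(codes: np.ndarray, l: int) -> np.ndarray:
    """Reverse complement of packed l-mer codes."""
    c = np.asarray(codes, dtype=np.uint32).copy()
    out = np.zeros_like(c)
    for _ in range(l):
        out = (out << np.uint32(2)) | (np.uint32(3) ^ (c & np.uint32(3)))
        c >>= np.uint32(2)
    return out


def decode_codes(codes: np.ndarray, l: int) -> list[str]:
    codes = np.asarray(codes, dtype=np.uint64)
    chars = np.empty((len(codes), l), dtype="U1")
    bases = np.array(list(DNA_ALPHABET))
    for j in range(l):
        chars[:, l - 1 - j] = bases[(codes >> np.uint64(2 * j)) & np.uint64(3)]
    return ["".join(row) for row in chars]


# ---------------------------------------------------------------------------
# parameters and kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GkmParams:
    """Gapped k-mer SVM hyperparameters.

    ``word_length`` (l) is the full word size, ``k`` the number of informative
    (ungapped) positions, ``max_mismatch`` the truncation of the mismatch
    profile (``None`` = untruncated, i.e. l - k).
    """

    word_length: int = 11
    k: int = 7
    max_mismatch: int | None = None
    both_strands: bool = True
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        l, k = self.word_length, self.k
        if not (1 <= k <= l <= 16):
            raise ValueError(f"require 1 <= k <= l <= 16, got l={l}, k={k}")
        if self.max_mismatch is not None and not (0 <= self.max_mismatch <= l - k):
            raise ValueError(f"max_mismatch must lie in [0, {l - k}]")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")

    @property
    def dmax(self) -> int:
        return self.word_length - self.k if self.max_mismatch is None else self.max_mismatch

    def coeff_table(self) -> np.ndarray:
        """Pair contribution C(l - m, k) for m = 0..dmax."""
        return np.array(
            [gkm_pair_contribution(m, self.word_length, self.k)
             for m in range(self.dmax + 1)], dtype=np.float64)


def gkm_pair_contribution(m: int, l: int, k: int) -> int:
    """Gapped k-mers shared by two l-mers at Hamming distance m: C(l-m, k)."""
    if not 0 <= m <= l:
        raise ValueError(f"mismatch count {m} outside [0, {l}]")
    return comb(l - m, k) if l - m >= k else 0


def _seq_codes(seq: str, params: GkmParams) -> tuple[np.ndarray, np.ndarray]:
    """(forward codes, y-side codes) for one sequence under the strand policy."""
    fwd = sliding_codes(seq, params.word_length)
    if params.both_strands:
        both = np.concatenate([fwd, revcomp_codes(fwd, params.word_length)])
    else:
        both = fwd
    return fwd, both


def gkm_kernel(x: str, y: str, params: GkmParams, normalized: bool = True) -> float:
    """Gapped k-mer kernel between two sequences.

    Raw value: sum of C(l - m, k) over all l-mer pairs (both strands of ``y``
    when ``both_strands``).  Normalised: K(x,y)/sqrt(K(x,x) K(y,y)).
    """
    coeff = params.coeff_table()
    xf, xb = _seq_codes(x, params)
    yf, yb = _seq_codes(y, params)
    l, d = params.word_length, params.dmax
    raw = _kernel.pair_sum(xf, yb, coeff, d, l)
    if not normalized:
        return raw
    kxx = _kernel.pair_sum(xf, xb, coeff, d, l)
    kyy = _kernel.pair_sum(yf, yb, coeff, d, l)
    return raw / np.sqrt(kxx * kyy)


def _normalized_gram(seqs: Sequence[str], params: GkmParams) -> tuple[np.ndarray, np.ndarray]:
    """(normalised Gram matrix, raw self-kernel diagonal) over sequences."""
    coeff = params.coeff_table()
    fwd, both = zip(*(_seq_codes(s, params) for s in seqs))
    raw = _kernel.gram_matrix(list(fwd), list(both), coeff, params.dmax,
                              params.word_length)
    diag = np.diag(raw).copy()
    norm = raw / np.sqrt(np.outer(diag, diag))
    return norm, diag


def _normalized_cross(seqs: Sequence[str], model: "GkmModel") -> np.ndarray:
    """Normalised kernel between new sequences (rows) and support vectors."""
    p = model.params
    coeff = p.coeff_table()
    fwd, both = zip(*(_seq_codes(s, p) for s in seqs))
    raw = _kernel.cross_matrix(
        list(fwd), list(model._sv_both_codes), coeff, p.dmax, p.word_length)
    self_raw = np.array([
        _kernel.pair_sum(f, b, coeff, p.dmax, p.word_length)
        for f, b in zip(fwd, both)])
    return raw / np.sqrt(np.outer(self_raw, model._sv_self_raw))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class GkmModel:
    """A trained gapped k-mer SVM for one cell class."""

    params: GkmParams
    support_sequences: list[tuple[str, int]]  # (sequence, label in {+1, -1})
    dual_coefficients: np.ndarray             # alpha_i * y_i
    bias: float
    class_label: str = ""
    training_accuracy: float | None = None
    _sv_both_codes: list[np.ndarray] = field(default_factory=list, repr=False)
    _sv_self_raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dual_coefficients = np.asarray(self.dual_coefficients, dtype=float)
        if len(self.dual_coefficients) != len(self.support_sequences):
            raise ValueError("dual coefficients and support sequences misaligned")
        if not self._sv_both_codes:
            self._cache_codes()

    def _cache_codes(self) -> None:
        coeff = self.params.coeff_table()
        fwd, both = zip(*(_seq_codes(s, self.params) for s, _ in self.support_sequences))
        self._sv_both_codes = list(both)
        self._sv_self_raw = np.array([
            _kernel.pair_sum(f, b, coeff, self.params.dmax, self.params.word_length)
            for f, b in zip(fwd, both)])

    # -- serialisation ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {
                "word_length": self.params.word_length, "k": self.params.k,
                "max_mismatch": self.params.max_mismatch,
                "both_strands": self.params.both_strands, "svm_C": self.params.svm_C,
            },
            "class_label": self.class_label,
            "bias": self.bias,
            "training_accuracy": self.training_accuracy,
            "support_sequences": [[s, int(y)] for s, y in self.support_sequences],
            "dual_coefficients": self.dual_coefficients.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GkmModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            params=GkmParams(**payload["params"]),
            support_sequences=[(s, int(y)) for s, y in payload["support_sequences"]],
            dual_coefficients=np.array(payload["dual_coefficients"]),
            bias=float(payload["bias"]),
            class_label=payload.get("class_label", ""),
            training_accuracy=payload.get("training_accuracy"),
        )


def train_model(positives: Sequence[str], negatives: Sequence[str],
                params: GkmParams, seed: int = 0, class_label: str = "",
                gram: np.ndarray | None = None) -> GkmModel:
    """Fit a soft-margin SVM on the precomputed normalised gkm kernel matrix.

    ``gram`` may be supplied to reuse an already-computed normalised kernel
    over ``positives + negatives`` (in that order), e.g. from cross-validation.
    """
    positives, negatives = list(positives), list(negatives)
    if not positives or not negatives:
        raise ValueError("both positive and negative sets must be non-empty")
    ratio = max(len(positives), len(negatives)) / min(len(positives), len(negatives))
    if ratio > 10:
        warnings.warn(f"label imbalance {ratio:.1f}:1 exceeds 10:1", stacklevel=2)
    seqs = positives + negatives
    labels = np.array([1] * len(positives) + [-1] * len(negatives))
    if gram is None:
        gram, _ = _normalized_gram(seqs, params)
    else:
        gram = np.array(gram, dtype=float, copy=True)
    gram[np.diag_indices_from(gram)] += 1e-8  # jitter
    try:
        np.linalg.cholesky(gram + 1e-6 * np.eye(len(gram)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("kernel matrix not positive semi-definite beyond "
                         "jitter tolerance") from exc
    svc = SVC(C=params.svm_C, kernel="precomputed", random_state=seed)
    svc.fit(gram, labels)
    accuracy = float((svc.predict(gram) == labels).mean())
    support = svc.support_
    model = GkmModel(
        params=params,
        support_sequences=[(seqs[i], int(labels[i])) for i in support],
        dual_coefficients=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        class_label=class_label,
        training_accuracy=accuracy,
    )
    return model


def predict_score(model: GkmModel, seq: str) -> float:
    """SVM decision value for one sequence; higher = more accessible-like."""
    return float(predict_scores(model, [seq])[0])


def predict_scores(model: GkmModel, seqs: Sequence[str]) -> np.ndarray:
    """Decision values for a batch of sequences."""
    if not seqs:
        return np.empty(0)
    knorm = _normalized_cross(list(seqs), model)
    return knorm @ model.dual_coefficients + model.bias


# ---------------------------------------------------------------------------
# l-mer weight table
# ---------------------------------------------------------------------------

@dataclass
class KmerWeightTable:
    """Decision-value weight (bias removed) for every l-mer over {A,C,G,T}.

    ``weights[code]`` is indexed by the packed l-mer code; string lookup is
    available via ``table["ACGT..."]``.
    """

    word_length: int
    weights: np.ndarray
    model_label: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != 4 ** self.word_length:
            raise ValueError(f"expected {4 ** self.word_length} weights")

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, kmer: str) -> float:
        code = sliding_codes(kmer, self.word_length)
        if len(code) != 1:
            raise ValueError(f"expected a single {self.word_length}-mer")
        return float(self.weights[code[0]])

    def to_tsv(self, path: str | Path, top: int | None = None) -> None:
        order = np.argsort(-self.weights, kind="stable")
        if top is not None:
            order = order[:top]
        kmers = decode_codes(order, self.word_length)
        with open(path, "w") as fh:
            fh.write("kmer\tweight\n")
            for kmer, code in zip(kmers, order):
                fh.write(f"{kmer}\t{self.weights[code]:.8g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, model_label: str = "") -> "KmerWeightTable":
        df = pd.read_csv(path, sep="\t")
        l = len(df["kmer"].iloc[0])
        weights = np.zeros(4 ** l)
        codes = np.concatenate([sliding_codes(k, l) for k in df["kmer"]])
        weights[codes] = df["weight"].to_numpy()
        return cls(word_length=l, weights=weights, model_label=model_label)


def _all_code_digits(l: int) -> list[np.ndarray]:
    """Base digit (0..3) of every l-mer code at each of the l 2-bit slots."""
    codes = np.arange(4 ** l, dtype=np.uint32)
    return [((codes >> np.uint32(2 * t)) & np.uint32(3)) for t in range(l)]


def extract_kmer_weights(model: GkmModel) -> KmerWeightTable:
    """Score every possible l-mer with the trained model, minus the bias.

    Uses the feature-map identity C(l-m, k) = number of k-position subsets on
    which the two words agree: the support-vector contribution factorises into
    one 4^k table per position subset, so the full 4^l table is filled with
    C(l, k) scatter/gather passes instead of an all-pairs scan.  Truncated
    mismatch profiles (max_mismatch < l - k) break the identity and fall back
    to the direct kernel path, which is only feasible for small l.
    """
    p = model.params
    l, k = p.word_length, p.k
    if l > 13:
        raise ValueError(f"4^{l} weight table infeasible")
    if p.dmax < l - k:
        return _extract_weights_direct(model)

    # per-support-vector l-mer codes weighted by alpha_i / sqrt(K(sv_i, sv_i))
    vcodes_parts, vw_parts = [], []
    for codes, alpha, self_raw in zip(model._sv_both_codes,
                                      model.dual_coefficients,
                                      model._sv_self_raw):
        vcodes_parts.append(codes)
        vw_parts.append(np.full(codes.size, alpha / np.sqrt(self_raw)))
    vcodes = np.concatenate(vcodes_parts)
    vw = np.concatenate(vw_parts)
    uniq, inverse = np.unique(vcodes, return_inverse=True)
    vw_uniq = np.bincount(inverse, weights=vw, minlength=uniq.size)

    u_digits = _all_code_digits(l)
    v_digits = [((uniq >> np.uint32(2 * t)) & np.uint32(3)) for t in range(l)]
    acc = np.zeros(4 ** l, dtype=np.float64)
    for subset in combinations(range(l), k):
        pat_u = np.zeros(4 ** l, dtype=np.uint32)
        pat_v = np.zeros(uniq.size, dtype=np.uint32)
        for t, pos in enumerate(subset):
            pat_u |= u_digits[pos] << np.uint32(2 * t)
            pat_v |= v_digits[pos] << np.uint32(2 * t)
        table = np.bincount(pat_v, weights=vw_uniq, minlength=4 ** k)
        acc += table[pat_u]

    # self-kernel of a bare l-mer: C(l,k) from the identity strand plus, with
    # both-strand counting, the contribution of its reverse complement
    coeff_full = np.array([gkm_pair_contribution(m, l, k) for m in range(l + 1)],
                          dtype=np.float64)
    self_raw_u = np.full(4 ** l, coeff_full[0])
    if p.both_strands:
        codes = np.arange(4 ** l, dtype=np.uint32)
        ham_rc = _kernel.hamming_codes(codes, revcomp_codes(codes, l), l)
        self_raw_u += coeff_full[ham_rc]
    weights = acc / np.sqrt(self_raw_u)
    return KmerWeightTable(word_length=l, weights=weights,
                           model_label=model.class_label)


def _extract_weights_direct(model: GkmModel) -> KmerWeightTable:
    l = model.params.word_length
    if l > 8:
        raise ValueError("direct weight extraction with a truncated mismatch "
                         "profile is only supported for l <= 8")
    kmers = decode_codes(np.arange(4 ** l, dtype=np.uint32), l)
    weights = predict_scores(model, kmers) - model.bias
    return KmerWeightTable(word_length=l, weights=np.asarray(weights),
                           model_label=model.class_label)


# ---------------------------------------------------------------------------
# cross-validation and cross-class scoring
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-fold ROC/PR curves plus pooled summary statistics."""

    fold_curves: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per fold
    fold_pr_curves: list[tuple[np.ndarray, np.ndarray]]  # (recall, precision)
    fold_auroc: list[float]
    fold_auprc: list[float]
    pooled_auroc: float
    pooled_auprc: float
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [{"fold": i + 1, "auroc": a, "auprc": p}
                for i, (a, p) in enumerate(zip(self.fold_auroc, self.fold_auprc))]
        rows.append({"fold": "pooled", "auroc": self.pooled_auroc,
                     "auprc": self.pooled_auprc})
        return pd.DataFrame(rows)


def cross_validate(positives: Sequence[str], negatives: Sequence[str],
                   params: GkmParams, folds: int = 5, seed: int = 0,
                   gram: np.ndarray | None = None) -> CvResult:
    """Stratified k-fold cross-validation on the precomputed kernel matrix.

    ``gram`` may be supplied to reuse an already-computed normalised kernel
    over ``positives + negatives`` (in that order).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    positives, negatives = list(positives), list(negatives)
    if min(len(positives), len(negatives)) < folds:
        raise ValueError("need at least `folds` examples per class")
    seqs = positives + negatives
    labels = np.array([1] * len(positives) + [-1] * len(negatives))
    if gram is None:
        gram, _ = _normalized_gram(seqs, params)
    gram = gram.copy()
    gram[np.diag_indices_from(gram)] += 1e-8

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_scores = np.empty(len(seqs))
    pooled_labels = np.empty(len(seqs), dtype=int)
    curves, pr_curves, aurocs, auprcs = [], [], [], []
    cursor = 0
    for train_idx, test_idx in skf.split(np.zeros(len(seqs)), labels):
        svc = SVC(C=params.svm_C, kernel="precomputed", random_state=seed)
        svc.fit(gram[np.ix_(train_idx, train_idx)], labels[train_idx])
        scores = svc.decision_function(gram[np.ix_(test_idx, train_idx)])
        fpr, tpr, _ = roc_curve(labels[test_idx], scores)
        prec, rec, _ = precision_recall_curve(labels[test_idx], scores)
        curves.append((fpr, tpr))
        pr_curves.append((rec, prec))
        aurocs.append(float(auc(fpr, tpr)))
        auprcs.append(float(average_precision_score(labels[test_idx], scores)))
        pooled_scores[cursor:cursor + len(test_idx)] = scores
        pooled_labels[cursor:cursor + len(test_idx)] = labels[test_idx]
        cursor += len(test_idx)
    fpr, tpr, _ = roc_curve(pooled_labels, pooled_scores)
    pooled_auroc = float(auc(fpr, tpr))
    pooled_auprc = float(average_precision_score(pooled_labels, pooled_scores))
    return CvResult(fold_curves=curves, fold_pr_curves=pr_curves,
                    fold_auroc=aurocs, fold_auprc=auprcs,
                    pooled_auroc=pooled_auroc, pooled_auprc=pooled_auprc,
                    seed=seed)


def cross_class_score_matrix(
    models: Sequence[GkmModel],
    test_sets: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, list[str], np.ndarray | None]:
    """Mean decision value of every model over every class's test peak set.

    Returns (matrix, row order, linkage): rows are peak sets, columns models,
    both ordered by average-linkage hierarchical clustering of the rows on
    correlation distance (identity order when fewer than 3 rows).
    """
    for label, seqs in test_sets.items():
        if len(seqs) == 0:
            raise ValueError(f"empty test set {label!r}")
    row_labels = list(test_sets.keys())
    col_labels = [m.class_label or f"model_{i}" for i, m in enumerate(models)]
    matrix = np.empty((len(row_labels), len(models)))
    for j, model in enumerate(models):
        for i, label in enumerate(row_labels):
            matrix[i, j] = float(np.mean(predict_scores(model, list(test_sets[label]))))
    df = pd.DataFrame(matrix, index=row_labels, columns=col_labels)
    if len(row_labels) < 3:
        return df, row_labels, None
    dist = pdist(matrix, metric="correlation")
    linkage = hierarchy.linkage(dist, method="average")
    order = [row_labels[i] for i in hierarchy.leaves_list(linkage)]
    ordered = df.loc[order]
    if set(row_labels) == set(col_labels):
        ordered = ordered[order]
    return ordered, order, linkage
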
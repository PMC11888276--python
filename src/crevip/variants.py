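"""deltaSVM-style Variant Impact Prediction (VIP).

A sequence's additive score is the sum of its sliding l-mer weights from a
trained model's weight table.  The impact of a variant is the difference of
additive scores between the variant and reference sequence; for an SNV only
the <= l windows covering the edited base change, so the score is computed
from those windows alone (and is exactly equal to the full rescore
difference).  Negative VIP predicts loss of regulatory activity under the
model's cell class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gkm import KmerWeightTable, encode_sequence
from .io import DNA_ALPHABET, GenomicRegion, MotifPFM, VariantRecord, extract_sequence
from .vocabulary import _window_scores, match_pwm_to_kmer

log = logging.getLogger(__name__)

_N_SENTINEL = 255


def _encode_allow_n(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), _N_SENTINEL, dtype=np.uint8)
    for i, base in enumerate(DNA_ALPHABET):
        out[arr == ord(base)] = i
    if ((out == _N_SENTINEL) & (arr != ord("N"))).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return out


# ---------------------------------------------------------------------------
# additive scoring and deltaSVM
# ---------------------------------------------------------------------------

def score_sequence_additive(table: KmerWeightTable, seq: str) -> float:
    """Sum of weight(u) over all sliding l-mers u of the sequence."""
    from .gkm import sliding_codes

    codes = sliding_codes(seq, table.word_length)
    return float(table.weights[codes].sum())


def delta_svm_snv(table: KmerWeightTable, seq: str, pos: int, alt: str) -> float:
    """VIP score of a single-nucleotide variant within ``seq``.

    Sums weight(window_alt) - weight(window_ref) over the windows covering
    ``pos``; identical to rescoring the whole edited sequence.
    """
    l = table.word_length
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    ref = seq[pos].upper()
    alt = alt.upper()
    if alt == ref:
        warnings.warn("alt equals ref; VIP is 0", stacklevel=2)
        return 0.0
    if alt not in DNA_ALPHABET:
        raise ValueError(f"bad alternate base {alt!r}")
    lo = max(0, pos - l + 1)
    hi = min(pos, len(seq) - l)
    if hi < lo:
        raise ValueError("no full window covers the variant position")
    window_ref = seq[lo : hi + l]
    window_alt = (seq[lo:pos] + alt + seq[pos + 1 : hi + l])
    return (score_sequence_additive(table, window_alt)
            - score_sequence_additive(table, window_ref))


def delta_svm_indel(table: KmerWeightTable, ref_seq: str, alt_seq: str) -> float:
    """VIP of an arbitrary edit: full additive rescore of alt minus ref."""
    return (score_sequence_additive(table, alt_seq)
            - score_sequence_additive(table, ref_seq))


# ---------------------------------------------------------------------------
# saturation mutagenesis
# ---------------------------------------------------------------------------

@dataclass
class VipTable:
    """Saturation-mutagenesis VIP scores for one region under one model.

    ``vip`` has shape (width, 4): entry [p, b] is the VIP of substituting
    base b at position p; the reference base's own column (and any position
    whose covering windows all contain N) is NaN.
    """

    region: GenomicRegion
    ref_sequence: str
    vip: np.ndarray
    model_label: str = ""

    @property
    def n_entries(self) -> int:
        return int(np.isfinite(self.vip).sum())

    def entries(self) -> pd.DataFrame:
        rows = []
        for p in range(len(self.ref_sequence)):
            for b, base in enumerate(DNA_ALPHABET):
                v = self.vip[p, b]
                if np.isfinite(v):
                    rows.append((p, self.ref_sequence[p], base, float(v)))
        return pd.DataFrame(rows, columns=["pos", "ref", "alt", "vip"])


def saturation_mutagenesis(table: KmerWeightTable, region: GenomicRegion,
                           genome: Mapping[str, str] | None = None,
                           sequence: str | None = None) -> VipTable:
    """VIP of every possible single-nucleotide substitution in a region.

    Vectorised over windows: for window code c with base digit d at in-window
    offset j, the code of the same window carrying alternate digit b is
    ``c XOR ((d XOR b) << 2(l-1-j))``, so each (position, alternate) cell
    accumulates weight lookups without re-encoding sequences.
    """
    if sequence is None:
        if genome is None:
            raise ValueError("supply either genome or sequence")
        sequence = extract_sequence(genome, region.chrom, region.start, region.end)
    sequence = sequence.upper()
    l = table.word_length
    L = len(sequence)
    if L < l:
        raise ValueError(f"region of width {L} shorter than word length {l}")
    digits = _encode_allow_n(sequence)
    n_positions = L - l + 1
    valid_digits = np.where(digits == _N_SENTINEL, 0, digits)
    codes = np.zeros(n_positions, dtype=np.uint32)
    for j in range(l):
        codes = (codes << np.uint32(2)) | valid_digits[j : j + n_positions].astype(np.uint32)
    window_ok = np.ones(n_positions, dtype=bool)
    for j in range(l):
        window_ok &= digits[j : j + n_positions] != _N_SENTINEL
    if not window_ok.all():
        log.info("region %s:%d-%d: %d windows skipped for N",
                 region.chrom, region.start, region.end, int((~window_ok).sum()))

    ref_w = table.weights[codes]
    vip = np.zeros((L, 4))
    touched = np.zeros((L, 4), dtype=bool)
    w_idx = np.arange(n_positions)
    for j in range(l):
        shift = np.uint32(2 * (l - 1 - j))
        p = w_idx + j
        d = digits[j : j + n_positions]
        ok = window_ok & (d != _N_SENTINEL)
        if not ok.any():
            continue
        for delta in (1, 2, 3):
            alt_codes = codes[ok] ^ (np.uint32(delta) << shift)
            b = d[ok] ^ delta
            np.add.at(vip, (p[ok], b), table.weights[alt_codes] - ref_w[ok])
            touched[p[ok], b] = True
    vip[~touched] = np.nan
    for p in range(L):  # the reference base itself is not a variant
        if digits[p] != _N_SENTINEL:
            vip[p, digits[p]] = np.nan
        else:
            vip[p, :] = np.nan
    return VipTable(region=region, ref_sequence=sequence, vip=vip,
                    model_label=table.model_label)


def summed_vip_track(vip: VipTable) -> dict[tuple[str, int], float]:
    """Per-position sum of the three alternate-allele VIPs (bedGraph-ready)."""
    track: dict[tuple[str, int], float] = {}
    for p in range(len(vip.ref_sequence)):
        row = vip.vip[p]
        if np.isfinite(row).any():
            track[(vip.region.chrom, vip.region.start + p)] = float(np.nansum(row))
    return track


# ---------------------------------------------------------------------------
# motif occurrences and VIP profiles
# ---------------------------------------------------------------------------

@dataclass
class MotifOccurrence:
    """A PWM hit at genomic coordinates (0-based half-open)."""

    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float


def scan_motif_occurrences(regions: Sequence[GenomicRegion],
                           genome: Mapping[str, str], pfm: MotifPFM,
                           threshold_frac: float = 0.8) -> list[MotifOccurrence]:
    """All PWM hits within the region set; palindromic double hits at one
    locus collapse to the forward-strand occurrence."""
    occurrences: list[MotifOccurrence] = []
    for region in regions:
        seq = extract_sequence(genome, region.chrom, region.start, region.end)
        hits = match_pwm_to_kmer(pfm, seq, threshold_frac)
        by_offset: dict[int, tuple[int, str, float]] = {}
        for off, strand, score in hits:
            prev = by_offset.get(off)
            if prev is None or (prev[1] == "-" and strand == "+"):
                by_offset[off] = (off, strand, score)
        for off, strand, score in by_offset.values():
            occurrences.append(MotifOccurrence(
                motif_id=pfm.id, chrom=region.chrom,
                start=region.start + off, end=region.start + off + pfm.length,
                strand=strand, score=score))
    return occurrences


@dataclass
class MotifVipProfile:
    """Mean VIP by offset relative to the motif start, in motif orientation."""

    motif_id: str
    model_label: str
    offsets: np.ndarray    # -window .. motif_len - 1 + window
    mean_vip: np.ndarray
    n_occurrences: int

    def core_mean(self, motif_length: int) -> float:
        """Mean VIP over the motif core (offsets 0 .. motif_length - 1)."""
        mask = (self.offsets >= 0) & (self.offsets < motif_length)
        return float(np.nanmean(self.mean_vip[mask]))

    def flank_mean(self, motif_length: int) -> float:
        mask = (self.offsets < 0) | (self.offsets >= motif_length)
        return float(np.nanmean(self.mean_vip[mask]))


def motif_vip_profile(vips: Sequence[VipTable],
                      occurrences: Sequence[MotifOccurrence],
                      window: int = 30) -> MotifVipProfile:
    """Average VIP of all variants around each motif occurrence.

    Offsets are in motif orientation: minus-strand occurrences are flipped so
    offset 0 is always the motif's 5' end.  Occurrences not covered by any
    VIP table are skipped with a log message.
    """
    if not occurrences:
        raise ValueError("no motif occurrences supplied")
    motif_len = occurrences[0].end - occurrences[0].start
    offsets = np.arange(-window, motif_len + window)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=int)
    by_chrom: dict[str, list[VipTable]] = {}
    for v in vips:
        by_chrom.setdefault(v.region.chrom, []).append(v)
    used = 0
    skipped = 0
    for occ in occurrences:
        cover = None
        for v in by_chrom.get(occ.chrom, []):
            if v.region.start <= occ.start and occ.end <= v.region.end:
                cover = v
                break
        if cover is None:
            skipped += 1
            continue
        used += 1
        for i, t in enumerate(offsets):
            pos = occ.start + t if occ.strand != "-" else occ.end - 1 - t
            rel = pos - cover.region.start
            if not 0 <= rel < len(cover.ref_sequence):
                continue
            row = cover.vip[rel]
            finite = np.isfinite(row)
            if finite.any():
                sums[i] += row[finite].sum()
                counts[i] += int(finite.sum())
    if skipped:
        log.info("motif %s: %d occurrences outside any scored region",
                 occurrences[0].motif_id, skipped)
    if used == 0:
        raise ValueError("no occurrence is covered by a VIP table")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    model_label = vips[0].model_label if vips else ""
    return MotifVipProfile(motif_id=occurrences[0].motif_id,
                           model_label=model_label, offsets=offsets,
                           mean_vip=mean, n_occurrences=used)


# ---------------------------------------------------------------------------
# external variant tables
# ---------------------------------------------------------------------------

def score_variant_table(tables: Mapping[str, KmerWeightTable],
                        variants: Sequence[VariantRecord],
                        genome: Mapping[str, str], flank_context: int = 150,
                        pfms: Sequence[MotifPFM] | None = None,
                        threshold_frac: float = 0.8) -> pd.DataFrame:
    """VIP of each variant under each model, with optional motif annotation.

    SNVs are scored in place within a ±``flank_context`` window; indels by
    rescoring the whole edited context.  The reference allele must match the
    genome.
    """
    rows = []
    for var in variants:
        contig = genome[var.chrom]
        ref_at = contig[var.pos : var.pos + len(var.ref_allele)].upper()
        if ref_at != var.ref_allele:
            raise ValueError(f"variant {var.id}: ref allele {var.ref_allele!r} "
                             f"does not match genome ({ref_at!r})")
        lo = max(0, var.pos - flank_context)
        hi = min(len(contig), var.pos + len(var.ref_allele) + flank_context)
        ctx = contig[lo:hi].upper()
        rel = var.pos - lo
        alt_ctx = ctx[:rel] + var.alt_allele + ctx[rel + len(var.ref_allele):]
        row: dict[str, object] = {"id": var.id, "chrom": var.chrom,
                                  "pos": var.pos, "ref": var.ref_allele,
                                  "alt": var.alt_allele}
        for label, table in tables.items():
            if var.is_snv:
                row[f"vip_{label}"] = delta_svm_snv(table, ctx, rel, var.alt_allele)
            else:
                row[f"vip_{label}"] = delta_svm_indel(table, ctx, alt_ctx)
        if pfms:
            row["ref_motifs"] = _annotate_motifs(ctx, pfms, threshold_frac)
            row["alt_motifs"] = _annotate_motifs(alt_ctx, pfms, threshold_frac)
        rows.append(row)
    return pd.DataFrame(rows)


def _annotate_motifs(seq: str, pfms: Sequence[MotifPFM],
                     threshold_frac: float) -> str:
    names = sorted({pfm.name for pfm in pfms
                    if match_pwm_to_kmer(pfm, seq, threshold_frac)})
    return ",".join(names)
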
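"""Training-set curation: summit extension, universal-region removal,
top-N selection, train/outgroup splitting, cross-class test-set filtering,
and GC-matched negative sampling.

The curation order is: extend summits to fixed-width candidate CREs, remove
regions accessible in every cell class (housekeeping), keep the top-scoring N
per class, split 80/20 into train/outgroup, cross-filter outgroups against
all classes' training regions, and draw background negatives matched to the
positives' GC histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomicRegion, extract_sequence

log = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """All peaks of one cell class at one stage of curation."""

    class_label: str
    regions: list[GenomicRegion]
    provenance: str = "raw"  # raw|extended|filtered|train|outgroup|negative

    def __len__(self) -> int:
        return len(self.regions)

    def widths(self) -> set[int]:
        return {r.width for r in self.regions}

    def sequences(self, genome: Mapping[str, str], skip_n: bool = True) -> list[str]:
        """Region sequences; windows containing N are skipped and logged."""
        out = []
        skipped = 0
        for r in self.regions:
            seq = extract_sequence(genome, r.chrom, r.start, r.end)
            if skip_n and "N" in seq:
                skipped += 1
                continue
            out.append(seq)
        if skipped:
            log.info("%s/%s: skipped %d regions containing N",
                     self.class_label, self.provenance, skipped)
        return out


@dataclass(frozen=True)
class SplitSpec:
    """Train/outgroup split parameters."""

    train_fraction: float = 0.8
    top_n: int = 25000
    seed: int = 0
    flank: int = 150

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        if self.top_n <= 0 or self.flank < 0:
            raise ValueError("top_n must be positive and flank non-negative")


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def _build_trees(regions: Iterable[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees


def _max_overlap(trees: dict[str, IntervalTree], region: GenomicRegion) -> int:
    tree = trees.get(region.chrom)
    if tree is None:
        return 0
    best = 0
    for hit in tree.overlap(region.start, region.end):
        best = max(best, min(region.end, hit.end) - max(region.start, hit.begin))
    return best


# ---------------------------------------------------------------------------
# curation operations
# ---------------------------------------------------------------------------

def extend_summits(peaks: Sequence[GenomicRegion], flank: int,
                   contig_lengths: Mapping[str, int] | None = None,
                   class_label: str = "") -> PeakSet:
    """Extend each summit by ``flank`` bp on both sides (width 2*flank + 1).

    Regions that would be clipped at a contig boundary are dropped and logged,
    so every emitted region has identical width.
    """
    out: list[GenomicRegion] = []
    dropped = 0
    for peak in peaks:
        if peak.summit is None:
            raise ValueError(f"peak {peak.name} at {peak.chrom}:{peak.start} has no summit")
        start = peak.summit - flank
        end = peak.summit + flank + 1
        limit = contig_lengths.get(peak.chrom) if contig_lengths else None
        if start < 0 or (limit is not None and end > limit):
            dropped += 1
            continue
        out.append(GenomicRegion(peak.chrom, start, end, score=peak.score,
                                 name=peak.name, strand=peak.strand, summit=peak.summit))
    if dropped:
        log.info("%s: dropped %d summit windows clipped at contig boundaries",
                 class_label, dropped)
    return PeakSet(class_label=class_label, regions=out, provenance="extended")


def remove_universal(peaksets: Sequence[PeakSet],
                     min_overlap_bp: int = 1) -> tuple[list[PeakSet], PeakSet]:
    """Split off 'universally accessible' regions.

    A region is universal iff it overlaps (by at least ``min_overlap_bp``)
    some region in every other class's set.  Universal regions are removed
    from every class and returned as one pooled set.
    """
    if len(peaksets) < 2:
        raise ValueError("universality is undefined for a single peak set")
    trees = {ps.class_label: _build_trees(ps.regions) for ps in peaksets}
    filtered: list[PeakSet] = []
    universal: list[GenomicRegion] = []
    for ps in peaksets:
        keep, drop = [], []
        others = [trees[other.class_label] for other in peaksets
                  if other.class_label != ps.class_label]
        for region in ps.regions:
            if all(_max_overlap(t, region) >= min_overlap_bp for t in others):
                drop.append(region)
            else:
                keep.append(region)
        log.info("%s: removed %d universal regions, %d remain",
                 ps.class_label, len(drop), len(keep))
        filtered.append(PeakSet(ps.class_label, keep, provenance="filtered"))
        universal.extend(drop)
    return filtered, PeakSet("universal", universal, provenance="filtered")


def select_top(peaks: PeakSet, n: int) -> PeakSet:
    """Keep the ``n`` highest-scoring regions; ties break by (chrom, start)."""
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = sorted(peaks.regions, key=lambda r: (-r.score, r.chrom, r.start))
    if len(ranked) < n:
        log.info("%s: only %d regions available for top-%d selection",
                 peaks.class_label, len(ranked), n)
    return PeakSet(peaks.class_label, ranked[:n], provenance=peaks.provenance)


def split_train_outgroup(peaks: PeakSet, spec: SplitSpec) -> tuple[PeakSet, PeakSet]:
    """Seeded shuffle, then floor(train_fraction * N) regions into train."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 regions to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(peaks.regions))
    n_train = int(np.floor(spec.train_fraction * len(peaks.regions)))
    train = [peaks.regions[i] for i in order[:n_train]]
    outgroup = [peaks.regions[i] for i in order[n_train:]]
    if not outgroup:
        warnings.warn(f"{peaks.class_label}: empty outgroup (train_fraction="
                      f"{spec.train_fraction})", stacklevel=2)
    return (PeakSet(peaks.class_label, train, provenance="train"),
            PeakSet(peaks.class_label, outgroup, provenance="outgroup"))


def build_uniform_testset(outgroups: Sequence[PeakSet], trainsets: Sequence[PeakSet],
                          min_overlap_bp: int = 1) -> list[PeakSet]:
    """Drop outgroup regions overlapping ANY class's training regions, so no
    model is evaluated on sequence any model trained on."""
    out_labels = sorted(ps.class_label for ps in outgroups)
    train_labels = sorted(ps.class_label for ps in trainsets)
    if out_labels != train_labels:
        raise ValueError(f"class labels differ: {out_labels} vs {train_labels}")
    all_train = [r for ps in trainsets for r in ps.regions]
    trees = _build_trees(all_train)
    result = []
    for ps in outgroups:
        keep = [r for r in ps.regions if _max_overlap(trees, r) < min_overlap_bp]
        removed = len(ps.regions) - len(keep)
        if removed:
            log.info("%s: removed %d outgroup regions colliding with training data",
                     ps.class_label, removed)
        result.append(PeakSet(ps.class_label, keep, provenance="outgroup"))
    return result


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def sample_gc_matched_negatives(positives: PeakSet, genome: Mapping[str, str],
                                exclude: Sequence[PeakSet], bin_width: float = 0.05,
                                seed: int = 0, ratio: float = 1.0) -> PeakSet:
    """Draw background windows GC-matched bin-for-bin to the positives.

    Candidates are width-w windows tiled every w/2 bp across the genome,
    minus anything overlapping an excluded (accessible) region or containing
    N.  Within each GC bin of width ``bin_width`` the required number of
    windows is sampled without replacement; a bin that cannot be filled is an
    error naming the bin.
    """
    widths = positives.widths()
    if len(widths) != 1:
        raise ValueError("positive regions must have uniform width")
    width = widths.pop()
    step = max(1, width // 2)
    exclude_trees = _build_trees(r for ps in exclude for r in ps.regions)

    pos_seqs = positives.sequences(genome)
    n_bins = int(np.ceil(1.0 / bin_width)) + 1
    pos_hist = np.zeros(n_bins, dtype=int)
    for seq in pos_seqs:
        pos_hist[int(gc_fraction(seq) / bin_width)] += 1
    target = np.round(pos_hist * ratio).astype(int)

    candidates: dict[int, list[GenomicRegion]] = {b: [] for b in range(n_bins)}
    for chrom in sorted(genome):
        contig = genome[chrom]
        for start in range(0, len(contig) - width + 1, step):
            region = GenomicRegion(chrom, start, start + width)
            if _max_overlap(exclude_trees, region) > 0:
                continue
            seq = contig[start:start + width]
            if "N" in seq:
                continue
            candidates[int(gc_fraction(seq) / bin_width)].append(region)

    rng = np.random.default_rng(seed)
    negatives: list[GenomicRegion] = []
    for b in range(n_bins):
        need = target[b]
        if need == 0:
            continue
        pool = candidates[b]
        if len(pool) < need:
            lo, hi = b * bin_width, (b + 1) * bin_width
            raise ValueError(
                f"GC bin [{lo:.2f},{hi:.2f}) exhausted: need {need}, "
                f"have {len(pool)} background candidates")
        chosen = rng.choice(len(pool), size=need, replace=False)
        for i in sorted(chosen):
            r = pool[i]
            negatives.append(replace(r, name=f"neg_{positives.class_label}_{len(negatives)}"))
    return PeakSet(positives.class_label, negatives, provenance="negative")


def manifest(peaksets: Sequence[PeakSet], genome: Mapping[str, str]):
    """Per-(class, partition) region counts and mean GC, as a DataFrame."""
    import pandas as pd

    rows = []
    for ps in peaksets:
        seqs = ps.sequences(genome)
        rows.append({
            "class": ps.class_label, "partition": ps.provenance,
            "n_regions": len(ps),
            "mean_gc": float(np.mean([gc_fraction(s) for s in seqs])) if seqs else float("nan"),
        })
    return pd.DataFrame(rows)
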
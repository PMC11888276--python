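"""Synthetic multi-class accessibility data with planted motif grammars.

The generator emulates the statistical structure of per-cell-class ATAC peak
sets: an i.i.d. background genome at a chosen GC content, fixed-width peak
regions per class carrying instances of that class's transcription-factor
motifs, a shared "universally accessible" fraction carrying a housekeeping
motif, decreasing peak scores, and a simulated reporter assay whose
expression is a known function of motif content.  Everything is seeded and
regenerates byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gkm import reverse_complement
from .io import DNA_ALPHABET, GenomicRegion, MotifPFM, VariantRecord
from .mpra import MpraRecord
from .peaks import PeakSet
from .vocabulary import _window_scores


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic multi-class benchmark."""

    n_classes: int = 3
    peaks_per_class: int = 500
    region_width: int = 301
    genome_length: int = 2_000_000
    background_gc: float = 0.41
    motifs_per_class: int = 2
    motif_length: int = 10
    insertions_per_peak: tuple[int, int] = (1, 3)
    shared_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction < 1:
            raise ValueError("shared_fraction must be in [0, 1)")
        if self.motif_length >= self.region_width:
            raise ValueError("motif_length must be smaller than region_width")


@dataclass
class MpraParams:
    """Generative parameters of the simulated reporter assay."""

    betas: dict[str, float]
    noise_sd: float = 0.15
    n_reps: int = 3
    hit_floor: float = 0.6  # hit fractions below this contribute no signal


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    motifs: list[MotifPFM]
    consensi: dict[str, str]
    grammars: dict[str, list[str]]        # class label -> motif ids
    signature_motif: dict[str, str]       # class label -> a class-private motif
    housekeeping_motif: str
    instances: list[tuple[str, str, str, int, int, str, str]]
    # (class, region_name, chrom, start, end, strand, motif_id)
    mpra: MpraParams | None = None

    def motif_by_id(self, motif_id: str) -> MotifPFM:
        for m in self.motifs:
            if m.id == motif_id:
                return m
        raise KeyError(motif_id)

    def instances_of(self, motif_id: str) -> list[tuple[str, str, str, int, int, str, str]]:
        return [inst for inst in self.instances if inst[6] == motif_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "motifs": [{"id": m.id, "name": m.name, "matrix": m.matrix.tolist()}
                       for m in self.motifs],
            "consensi": self.consensi,
            "grammars": self.grammars,
            "signature_motif": self.signature_motif,
            "housekeeping_motif": self.housekeeping_motif,
            "instances": [list(i) for i in self.instances],
            "mpra": None if self.mpra is None else {
                "betas": self.mpra.betas, "noise_sd": self.mpra.noise_sd,
                "n_reps": self.mpra.n_reps, "hit_floor": self.mpra.hit_floor},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        p = json.loads(Path(path).read_text())
        return cls(
            motifs=[MotifPFM(m["id"], m["name"], np.array(m["matrix"]))
                    for m in p["motifs"]],
            consensi=p["consensi"], grammars=p["grammars"],
            signature_motif=p["signature_motif"],
            housekeeping_motif=p["housekeeping_motif"],
            instances=[tuple(i) for i in p["instances"]],
            mpra=None if p["mpra"] is None else MpraParams(**p["mpra"]),
        )


# ---------------------------------------------------------------------------
# motif generation
# ---------------------------------------------------------------------------

def make_motif_set(n: int, length: int, seed: int = 0,
                   min_hamming: int | None = None,
                   name_prefix: str = "MOTIF") -> tuple[list[MotifPFM], dict[str, str]]:
    """Sharp, mutually distinct PFMs with per-column consensus probability
    drawn from U(0.80, 0.97) (average information content above 1 bit).

    Consensus strings are pairwise at Hamming distance >= length/2.
    """
    if length < 6:
        raise ValueError("motif_length must be at least 6")
    if min_hamming is None:
        min_hamming = length // 2
    rng = np.random.default_rng(seed)
    consensi: list[str] = []
    for _ in range(n):
        for attempt in range(2000):
            cand = "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))
            if all(sum(a != b for a, b in zip(cand, c)) >= min_hamming
                   for c in consensi):
                consensi.append(cand)
                break
        else:
            raise RuntimeError("could not generate sufficiently distinct consensi")
    pfms: list[MotifPFM] = []
    for idx, consensus in enumerate(consensi):
        matrix = np.zeros((4, length))
        for col, base in enumerate(consensus):
            p_cons = rng.uniform(0.80, 0.97)
            off = rng.dirichlet(np.ones(3)) * (1 - p_cons)
            probs = np.empty(4)
            oi = 0
            for b in range(4):
                if DNA_ALPHABET[b] == base:
                    probs[b] = p_cons
                else:
                    probs[b] = off[oi]
                    oi += 1
            matrix[:, col] = probs * 1000.0
        pfms.append(MotifPFM(id=f"{name_prefix}{idx}", name=f"TF{idx}",
                             matrix=matrix))
    return pfms, {p.id: c for p, c in zip(pfms, consensi)}


def default_grammars(n_classes: int, motifs_per_class: int) -> tuple[dict[str, list[int]], int]:
    """Class -> motif pool indices; classes 0 and 1 share their first motif
    (when possible), so related grammars exist for the clustering analyses."""
    grammars: dict[str, list[int]] = {}
    cursor = 0
    for c in range(n_classes):
        label = f"class{c}"
        if c == 1 and motifs_per_class >= 2:
            ids = [grammars["class0"][0]]
            ids += list(range(cursor, cursor + motifs_per_class - 1))
            cursor += motifs_per_class - 1
        else:
            ids = list(range(cursor, cursor + motifs_per_class))
            cursor += motifs_per_class
        grammars[label] = ids
    return grammars, cursor


# ---------------------------------------------------------------------------
# genome and peaks
# ---------------------------------------------------------------------------

def _sample_instance(pfm: MotifPFM, rng: np.random.Generator) -> str:
    probs = pfm.matrix / pfm.matrix.sum(axis=0, keepdims=True)
    return "".join(DNA_ALPHABET[rng.choice(4, p=probs[:, j])]
                   for j in range(pfm.length))


def _plant(genome: np.ndarray, seq: str, start: int, strand: str) -> None:
    if strand == "-":
        seq = reverse_complement(seq)
    from .gkm import encode_sequence
    genome[start : start + len(seq)] = encode_sequence(seq)


def simulate_genome_and_peaks(
    spec: SyntheticSpec,
) -> tuple[dict[str, str], list[PeakSet], GroundTruth]:
    """Generate the genome, per-class raw peak sets and the ground truth.

    Private peaks carry 1..insertions_per_peak instances of the class's
    motifs; floor(shared_fraction * peaks_per_class) universal peaks are
    identical across classes and carry a housekeeping motif.  Peak scores
    decrease with index within each class.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chr1"
    w = spec.region_width
    n_shared = int(np.floor(spec.shared_fraction * spec.peaks_per_class))
    n_private = spec.peaks_per_class - n_shared
    total_regions = spec.n_classes * n_private + n_shared

    stride = 2 * w
    n_slots = spec.genome_length // stride
    if n_slots < total_regions:
        raise ValueError(f"slot exhaustion: genome of length {spec.genome_length} "
                         f"holds {n_slots} slots but {total_regions} regions needed")

    gc = spec.background_gc
    genome = rng.choice(4, size=spec.genome_length,
                        p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]).astype(np.uint8)

    grammars_idx, n_pool = default_grammars(spec.n_classes, spec.motifs_per_class)
    pfms, consensi = make_motif_set(n_pool + 1, spec.motif_length,
                                    seed=int(rng.integers(2 ** 31)))
    housekeeping = pfms[-1]
    grammars = {label: [pfms[i].id for i in ids]
                for label, ids in grammars_idx.items()}
    signature = {}
    for label, ids in grammars.items():
        private = [m for m in ids
                   if sum(m in g for g in grammars.values()) == 1]
        signature[label] = private[-1] if private else ids[-1]

    slot_order = rng.permutation(n_slots)[:total_regions]
    instances: list[tuple[str, str, str, int, int, str, str]] = []

    def plant_peak(start: int, name: str, owner: str,
                   motif_ids: list[str]) -> None:
        lo_ins, hi_ins = spec.insertions_per_peak
        n_ins = int(rng.integers(lo_ins, hi_ins + 1))
        placed: list[tuple[int, int]] = []
        for _ in range(n_ins):
            motif_id = motif_ids[int(rng.integers(len(motif_ids)))]
            pfm = next(p for p in pfms if p.id == motif_id)
            for _attempt in range(50):
                off = int(rng.integers(0, w - pfm.length + 1))
                if all(off + pfm.length <= a or off >= b for a, b in placed):
                    break
            else:
                continue
            placed.append((off, off + pfm.length))
            strand = "+" if rng.random() < 0.5 else "-"
            inst_seq = _sample_instance(pfm, rng)
            _plant(genome, inst_seq, start + off, strand)
            instances.append((owner, name, chrom, start + off,
                              start + off + pfm.length, strand, motif_id))

    # shared (universal) regions first, then per-class private regions
    shared_regions: list[GenomicRegion] = []
    cursor = 0
    for i in range(n_shared):
        start = int(slot_order[cursor]) * stride
        cursor += 1
        name = f"universal{i}"
        plant_peak(start, name, "universal", [housekeeping.id])
        shared_regions.append(GenomicRegion(chrom, start, start + w, name=name,
                                            summit=start + w // 2))

    peaksets: list[PeakSet] = []
    for label in grammars:
        regions: list[GenomicRegion] = []
        for i in range(n_private):
            start = int(slot_order[cursor]) * stride
            cursor += 1
            name = f"{label}_peak{i}"
            plant_peak(start, name, label, grammars[label])
            regions.append(GenomicRegion(chrom, start, start + w, name=name,
                                         summit=start + w // 2))
        regions = regions + [GenomicRegion(r.chrom, r.start, r.end, name=r.name,
                                           summit=r.summit)
                             for r in shared_regions]
        order = rng.permutation(len(regions))
        scored = []
        for rank, idx in enumerate(order):
            r = regions[idx]
            scored.append(GenomicRegion(r.chrom, r.start, r.end,
                                        score=float(len(regions) - rank),
                                        name=r.name, summit=r.summit))
        peaksets.append(PeakSet(class_label=label, regions=scored,
                                provenance="raw"))

    genome_str = "".join(DNA_ALPHABET[b] for b in genome)
    truth = GroundTruth(
        motifs=pfms, consensi=consensi, grammars=grammars,
        signature_motif=signature, housekeeping_motif=housekeeping.id,
        instances=instances,
        mpra=MpraParams(betas={p.id: 1.0 for p in pfms}),
    )
    return {chrom: genome_str}, peaksets, truth


# ---------------------------------------------------------------------------
# simulated reporter assay
# ---------------------------------------------------------------------------

def _hit_fraction(seq: str, pfm: MotifPFM, floor: float = 0.0) -> float:
    """Best log-odds hit as a fraction of the PWM's maximum, hinged at
    ``floor``: fractions below the floor (chance-level matches) contribute 0,
    and above it the response rises linearly to 1 at a perfect match.

    The hinge is continuous, so reporter expression decreases strictly with
    planted-motif damage until the hit decays to background level, and a
    construct without the motif carries exactly zero signal.
    """
    from .gkm import encode_sequence

    digits = encode_sequence(seq)
    lo = pfm.log_odds()
    best = -np.inf
    for mat in (lo, lo[::-1, ::-1]):
        s = _window_scores(digits, mat)
        if len(s):
            best = max(best, float(s.max()))
    frac = best / pfm.max_score()
    if floor <= 0.0:
        return frac
    return max(0.0, frac - floor) / (1.0 - floor)


def expression_signal(seq: str, cell_class: str, truth: GroundTruth) -> float:
    """Noise-free reporter signal of a construct in one cell class."""
    params = truth.mpra
    if params is None:
        raise ValueError("ground truth carries no MPRA parameters")
    total = 0.0
    for motif_id in truth.grammars[cell_class]:
        pfm = truth.motif_by_id(motif_id)
        total += params.betas[motif_id] * _hit_fraction(seq, pfm, params.hit_floor)
    return total


def apply_edit(construct: str, variant: VariantRecord) -> str:
    ref_at = construct[variant.pos : variant.pos + len(variant.ref_allele)]
    if ref_at.upper() != variant.ref_allele:
        raise ValueError(f"variant {variant.id}: ref {variant.ref_allele!r} does "
                         f"not match construct ({ref_at!r})")
    return (construct[: variant.pos] + variant.alt_allele
            + construct[variant.pos + len(variant.ref_allele):])


def simulate_mpra(construct: str, variants: Sequence[VariantRecord],
                  truth: GroundTruth, n_reps: int | None = None,
                  noise_sd: float | None = None, seed: int = 0) -> list[MpraRecord]:
    """Simulated reporter expression changes for edits of one construct.

    Expression of a class is the sum over its motifs of beta times the best
    PWM hit fraction in the (edited) construct, plus Gaussian noise, averaged
    over replicates; the expression change is variant minus reference.
    """
    params = truth.mpra or MpraParams(betas={m.id: 1.0 for m in truth.motifs})
    n_reps = params.n_reps if n_reps is None else n_reps
    noise_sd = params.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    records: list[MpraRecord] = []
    for cell_class in truth.grammars:
        ref_signal = expression_signal(construct, cell_class, truth)
        ref_expr = ref_signal + float(rng.normal(0, noise_sd, size=n_reps).mean()) \
            if noise_sd > 0 else ref_signal
        for variant in variants:
            edited = apply_edit(construct, variant)
            signal = expression_signal(edited, cell_class, truth)
            noise = float(rng.normal(0, noise_sd, size=n_reps).mean()) if noise_sd > 0 else 0.0
            records.append(MpraRecord(
                variant_id=variant.id, cell_class=cell_class,
                expression_change=signal + noise - ref_expr,
                reference_expression=ref_expr))
    return records


def _draw_panel(seq: str, motif_positions: set[int], n_in_motif: int,
                n_background: int, rng: np.random.Generator, chrom: str,
                buffer: int = 5):
    import pandas as pd

    near = {p for mp in motif_positions for p in range(mp - buffer, mp + buffer + 1)}
    background_pos = [p for p in range(len(seq)) if p not in near]
    motif_pos_list = sorted(motif_positions)
    if len(motif_pos_list) < 1 or n_in_motif > len(motif_pos_list) * 3:
        raise ValueError("not enough planted-motif positions for the panel")
    if n_background > len(background_pos) * 3:
        raise ValueError("not enough background positions for the panel")

    def draw(pool: list[int], n: int, category: str, rows: list[dict]) -> None:
        combos = [(p, alt) for p in pool for alt in DNA_ALPHABET if alt != seq[p]]
        chosen = rng.choice(len(combos), size=n, replace=False)
        for idx in sorted(chosen):
            p, alt = combos[idx]
            rows.append({"id": f"{category}_{p}_{alt}", "chrom": chrom,
                         "pos": p, "ref": seq[p], "alt": alt,
                         "category": category})

    rows: list[dict] = []
    draw(motif_pos_list, n_in_motif, "in_motif", rows)
    draw(background_pos, n_background, "background", rows)
    return pd.DataFrame(rows)


def make_variant_panel(region: GenomicRegion, genome: Mapping[str, str],
                       truth: GroundTruth, n_in_motif: int, n_background: int,
                       seed: int = 0, buffer: int = 5):
    """SNV panel split between planted-motif cores and background positions.

    Positions are relative to the region start.  Returns a DataFrame with a
    ground-truth ``category`` column (in_motif / background).
    """
    from .io import extract_sequence

    rng = np.random.default_rng(seed)
    seq = extract_sequence(genome, region.chrom, region.start, region.end)
    motif_pos: set[int] = set()
    for _, _, chrom, start, end, _, _ in truth.instances:
        if chrom == region.chrom and start >= region.start and end <= region.end:
            motif_pos.update(range(start - region.start, end - region.start))
    return _draw_panel(seq, motif_pos, n_in_motif, n_background, rng,
                       region.chrom, buffer)


def make_reporter_construct(truth: GroundTruth, cell_class: str,
                            length: int = 230, seed: int = 0,
                            background_gc: float = 0.41,
                            ) -> tuple[str, dict[str, tuple[int, int]]]:
    """A reporter construct carrying one consensus instance of each of the
    class's motifs, evenly spaced on uniform background.

    Returns the sequence and the planted (start, end) site per motif id.
    """
    rng = np.random.default_rng(seed)
    gc = background_gc
    arr = rng.choice(4, size=length,
                     p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]).astype(np.uint8)
    motif_ids = truth.grammars[cell_class]
    sites: dict[str, tuple[int, int]] = {}
    gap = length // (len(motif_ids) + 1)
    from .gkm import encode_sequence
    for i, motif_id in enumerate(motif_ids):
        consensus = truth.consensi[motif_id]
        start = (i + 1) * gap - len(consensus) // 2
        arr[start : start + len(consensus)] = encode_sequence(consensus)
        sites[motif_id] = (start, start + len(consensus))
    return "".join(DNA_ALPHABET[b] for b in arr), sites


def construct_variant_panel(construct: str, sites: Mapping[str, tuple[int, int]],
                            n_in_motif: int, n_background: int, seed: int = 0,
                            buffer: int = 5):
    """SNV panel over a reporter construct, using its planted motif sites."""
    rng = np.random.default_rng(seed)
    motif_pos = {p for start, end in sites.values() for p in range(start, end)}
    return _draw_panel(construct, motif_pos, n_in_motif, n_background, rng,
                       "construct", buffer)
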
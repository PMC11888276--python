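"""End-to-end orchestration: simulate -> prepare -> train -> vip -> mpra.

Each stage reads the standard-format files of the previous stage and writes
its products with a provenance header, so runs are reproducible from the
config file and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gkm, io, mpra as mpra_mod, peaks as peaks_mod, simulate as sim
from . import variants as var_mod, vocabulary as vocab_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, loadable from a flat key=value file."""

    # inputs (simulate fills these in itself)
    genome: str = ""
    peaks: dict[str, str] = field(default_factory=dict)  # class label -> path
    motifs: str = ""
    whitelist: str = ""
    variants: str = ""
    mpra_table: str = ""
    construct: str = ""          # FASTA with the reporter construct
    # model hyperparameters
    word_length: int = 11
    k: int = 7
    max_mismatch: int = -1       # -1 = untruncated
    both_strands: bool = True
    svm_C: float = 1.0
    # curation
    train_fraction: float = 0.8
    top_n: int = 25000
    flank: int = 150
    min_overlap_bp: int = 1
    gc_bin_width: float = 0.05
    # downstream thresholds
    vocab_fraction: float = 0.01
    motif_threshold: float = 0.8
    profile_window: int = 30
    flank_context: int = 150
    folds: int = 5
    seed: int = 0
    # synthetic data
    n_classes: int = 3
    peaks_per_class: int = 500
    region_width: int = 301
    genome_length: int = 2_000_000
    background_gc: float = 0.41
    motifs_per_class: int = 2
    motif_length: int = 10
    insertions_min: int = 1
    insertions_max: int = 3
    shared_fraction: float = 0.1

    def gkm_params(self) -> gkm.GkmParams:
        return gkm.GkmParams(
            word_length=self.word_length, k=self.k,
            max_mismatch=None if self.max_mismatch < 0 else self.max_mismatch,
            both_strands=self.both_strands, svm_C=self.svm_C)

    def split_spec(self) -> peaks_mod.SplitSpec:
        return peaks_mod.SplitSpec(train_fraction=self.train_fraction,
                                   top_n=self.top_n, seed=self.seed,
                                   flank=self.flank)

    def synthetic_spec(self) -> sim.SyntheticSpec:
        return sim.SyntheticSpec(
            n_classes=self.n_classes, peaks_per_class=self.peaks_per_class,
            region_width=self.region_width, genome_length=self.genome_length,
            background_gc=self.background_gc,
            motifs_per_class=self.motifs_per_class,
            motif_length=self.motif_length,
            insertions_per_peak=(self.insertions_min, self.insertions_max),
            shared_fraction=self.shared_fraction, seed=self.seed)

    _PATH_FIELDS = ("genome", "peaks", "motifs", "whitelist", "variants",
                    "mpra_table", "construct")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (input file paths excluded, so
        the hash is stable across working directories)."""
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in self._PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def provenance(self, stage: str) -> str:
        return f"crevip {stage} seed={self.seed} config={self.config_hash()}"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls()
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "peaks":
                entries = {}
                for item in value.split(","):
                    label, _, p = item.partition(":")
                    entries[label.strip()] = p.strip()
                cfg.peaks = entries
                continue
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in {"1", "true", "yes"})
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{header}\n")
        df.to_csv(fh, sep="\t", index=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, outdir: str | Path) -> PipelineConfig:
    """Generate the synthetic study inputs and return a config pointing at them."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, peaksets, truth = sim.simulate_genome_and_peaks(config.synthetic_spec())
    io.write_fasta(genome, outdir / "genome.fa")
    peak_paths = {}
    for ps in peaksets:
        path = outdir / f"{ps.class_label}.narrowPeak"
        io.write_narrowpeak(ps.regions, path)
        peak_paths[ps.class_label] = str(path)
    io.write_jaspar_pfm(truth.motifs, outdir / "motifs.jaspar")
    (outdir / "whitelist.txt").write_text(
        "".join(f"{m.name}\n" for m in truth.motifs))
    truth.to_json(outdir / "ground_truth.json")
    updated = dataclasses.replace(
        config, genome=str(outdir / "genome.fa"),
        motifs=str(outdir / "motifs.jaspar"),
        whitelist=str(outdir / "whitelist.txt"))
    updated.peaks = peak_paths
    return updated


def run_prepare(config: PipelineConfig, outdir: str | Path) -> dict:
    """Summit extension, universal removal, top-N, split, uniform test sets,
    GC-matched negatives; writes per-class BED + FASTA and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.genome or not Path(config.genome).exists():
        raise FileNotFoundError(f"genome FASTA not found: {config.genome!r}")
    genome = io.read_fasta(config.genome)
    contig_lengths = {c: len(s) for c, s in genome.items()}
    spec = config.split_spec()

    raw_sets, extended = [], []
    for label, path in sorted(config.peaks.items()):
        raw = io.read_narrowpeak(path)
        raw_sets.append(peaks_mod.PeakSet(label, raw, provenance="raw"))
        extended.append(peaks_mod.extend_summits(raw, spec.flank,
                                                 contig_lengths, label))
    filtered, universal = peaks_mod.remove_universal(extended,
                                                     config.min_overlap_bp)
    trains, outgroups = [], []
    for ps in filtered:
        top = peaks_mod.select_top(ps, spec.top_n)
        train, outgroup = peaks_mod.split_train_outgroup(top, spec)
        trains.append(train)
        outgroups.append(outgroup)
    uniform = peaks_mod.build_uniform_testset(outgroups, trains,
                                              config.min_overlap_bp)
    negatives = [
        peaks_mod.sample_gc_matched_negatives(
            train, genome, exclude=extended, bin_width=config.gc_bin_width,
            seed=config.seed + i)
        for i, train in enumerate(trains)]

    all_sets = trains + uniform + negatives
    for ps in all_sets:
        stem = f"{ps.class_label}.{ps.provenance}"
        io.write_bed(ps.regions, outdir / f"{stem}.bed",
                     header=config.provenance("prepare"))
        io.write_fasta({r.name: io.extract_sequence(genome, r.chrom, r.start, r.end)
                        for r in ps.regions}, outdir / f"{stem}.fa")
    manifest = peaks_mod.manifest(all_sets, genome)
    _write_tsv(manifest, outdir / "manifest.tsv", config.provenance("prepare"))
    return {"train": trains, "outgroup": uniform, "negative": negatives,
            "universal": universal, "genome": genome, "manifest": manifest}


def run_train_and_evaluate(config: PipelineConfig, outdir: str | Path,
                           prepared: dict | None = None) -> dict:
    """One model per class with five-fold CV, the cross-class score matrix
    and per-model l-mer weight tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if prepared is None:
        prepared = _load_prepared(config, outdir)
    params = config.gkm_params()
    genome = prepared["genome"]
    models, cv_rows, weight_tables = [], [], {}
    for train, neg in zip(prepared["train"], prepared["negative"]):
        label = train.class_label
        pos_seqs = train.sequences(genome)
        neg_seqs = neg.sequences(genome)
        if not pos_seqs:
            raise ValueError(f"class {label}: empty training set")
        from .gkm import _normalized_gram
        gram, _ = _normalized_gram(pos_seqs + neg_seqs, params)
        cv = gkm.cross_validate(pos_seqs, neg_seqs, params,
                                folds=config.folds, seed=config.seed, gram=gram)
        model = gkm.train_model(pos_seqs, neg_seqs, params, seed=config.seed,
                                class_label=label, gram=gram)
        model.to_json(outdir / f"{label}.model.json")
        table = gkm.extract_kmer_weights(model)
        weight_tables[label] = table
        if params.word_length <= 8:
            table.to_tsv(outdir / f"{label}.weights.tsv")
        summary = cv.summary()
        summary.insert(0, "class", label)
        cv_rows.append(summary)
        curve_rows = [
            {"class": label, "fold": fold + 1, "fpr": float(f), "tpr": float(t)}
            for fold, (fpr, tpr) in enumerate(cv.fold_curves)
            for f, t in zip(fpr, tpr)]
        _write_tsv(pd.DataFrame(curve_rows), outdir / f"{label}.roc.tsv",
                   config.provenance("train"))
        models.append(model)
    cv_df = pd.concat(cv_rows, ignore_index=True)
    _write_tsv(cv_df, outdir / "cv_summary.tsv", config.provenance("train"))

    test_seqs = {ps.class_label: ps.sequences(genome)
                 for ps in prepared["outgroup"]}
    matrix, order, linkage = gkm.cross_class_score_matrix(models, test_seqs)
    _write_tsv(matrix, outdir / "cross_class_matrix.tsv",
               config.provenance("train") + f" row_order={','.join(order)}")
    return {"models": models, "cv": cv_df, "matrix": matrix, "order": order,
            "linkage": linkage, "weights": weight_tables}


def run_vip(config: PipelineConfig, outdir: str | Path, trained: dict,
            prepared: dict) -> dict:
    """Vocabulary + motif z-scores, saturation VIP tables and summed tracks,
    motif-centred profiles, and external variant-table scoring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = prepared["genome"]
    pfms = io.read_jaspar_pfm(config.motifs) if config.motifs else []
    whitelist = (io.read_tf_whitelist(config.whitelist)
                 if config.whitelist else set())
    results: dict = {}

    tops = {}
    for label, table in trained["weights"].items():
        ranked = vocab_mod.rank_vocabulary(table)
        tops[label] = vocab_mod.top_fraction(ranked, config.vocab_fraction)
    results["tops"] = tops
    if pfms and len(tops) >= 2:
        counts = vocab_mod.count_matrix(tops, pfms, whitelist,
                                        config.motif_threshold)
        enriched = vocab_mod.motif_zscores(counts)
        _write_tsv(enriched.counts, outdir / "motif_counts.tsv",
                   config.provenance("vip"))
        _write_tsv(enriched.zscores, outdir / "motif_zscores.tsv",
                   config.provenance("vip"))
        results["motif_matrix"] = enriched

    vips_by_model: dict[str, list] = {}
    for label, table in trained["weights"].items():
        vips = []
        track: dict = {}
        for ps in prepared["outgroup"]:
            for region in ps.regions:
                seq = io.extract_sequence(genome, region.chrom, region.start,
                                          region.end)
                vip = var_mod.saturation_mutagenesis(table, region,
                                                     sequence=seq)
                vips.append(vip)
                track.update(var_mod.summed_vip_track(vip))
        vips_by_model[label] = vips
        io.write_bedgraph(track, outdir / f"{label}.summed_vip.bedGraph",
                          header=config.provenance("vip"))
    results["vips"] = vips_by_model

    if pfms:
        profile_rows = []
        outgroup_regions = [r for ps in prepared["outgroup"] for r in ps.regions]
        for pfm in pfms:
            occurrences = var_mod.scan_motif_occurrences(
                outgroup_regions, genome, pfm, config.motif_threshold)
            if not occurrences:
                continue
            for label, vips in vips_by_model.items():
                try:
                    profile = var_mod.motif_vip_profile(
                        vips, occurrences, window=config.profile_window)
                except ValueError:
                    continue
                for off, val in zip(profile.offsets, profile.mean_vip):
                    profile_rows.append({
                        "motif": pfm.id, "model": label, "offset": int(off),
                        "mean_vip": val, "n": profile.n_occurrences})
        if profile_rows:
            prof_df = pd.DataFrame(profile_rows)
            _write_tsv(prof_df, outdir / "motif_vip_profiles.tsv",
                       config.provenance("vip"))
            results["profiles"] = prof_df

    if config.variants and Path(config.variants).exists():
        variants = io.read_variant_table(config.variants)
        scored = var_mod.score_variant_table(
            trained["weights"], variants, genome,
            flank_context=config.flank_context, pfms=pfms or None,
            threshold_frac=config.motif_threshold)
        _write_tsv(scored, outdir / "variant_vip.tsv", config.provenance("vip"))
        results["variant_table"] = scored
    return results


def run_mpra(config: PipelineConfig, outdir: str | Path,
             variant_table: pd.DataFrame,
             class_map: dict[str, str] | None = None) -> dict:
    """Join scored variants with MPRA measurements and correlate per class."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.mpra_table or not Path(config.mpra_table).exists():
        log.info("no MPRA table supplied; stage skipped")
        return {}
    records = mpra_mod.read_mpra_table(config.mpra_table)
    if class_map is None:
        classes = {r.cell_class for r in records}
        class_map = {label: label for label in classes}
    joined = mpra_mod.join_vip_mpra(variant_table, records, class_map)
    corr = mpra_mod.correlation_by_class(joined)
    _write_tsv(joined, outdir / "mpra_joined.tsv", config.provenance("mpra"))
    _write_tsv(corr, outdir / "mpra_correlations.tsv", config.provenance("mpra"))
    return {"joined": joined, "correlations": corr}


def _load_prepared(config: PipelineConfig, outdir: Path) -> dict:
    genome = io.read_fasta(config.genome)
    out: dict = {"train": [], "outgroup": [], "negative": [], "genome": genome}
    for label in sorted(config.peaks):
        for part in ("train", "outgroup", "negative"):
            path = outdir / f"{label}.{part}.bed"
            if not path.exists():
                raise FileNotFoundError(f"prepared file missing: {path}")
            regions = io.read_narrowpeak(path)
            out[part].append(peaks_mod.PeakSet(label, regions, provenance=part))
    return out
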
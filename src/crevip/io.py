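"""Readers and writers for the external file formats the pipeline touches.

All coordinates are 0-based half-open internally (BED convention).  The only
place 1-based input is translated is :func:`to_zero_based`, which variant-table
reading goes through when ``one_based=True``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

DNA_ALPHABET = "ACGT"
STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A file violated the expected dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomicRegion:
    """A scored, stranded interval; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str = "."
    strand: str = "."
    summit: int | None = None  # absolute coordinate of the peak summit

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start in region {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise FormatError(f"empty/inverted region {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class MotifPFM:
    """A position frequency matrix over A,C,G,T (rows) by motif position (columns)."""

    id: str
    name: str
    matrix: np.ndarray  # shape (4, L), counts or frequencies
    pseudocount_frac: float = 0.01  # pseudocount = frac * column sum

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise FormatError(f"PFM {self.id}: matrix must be 4 x L")
        if (self.matrix < 0).any():
            raise FormatError(f"PFM {self.id}: negative entries")
        if (self.matrix.sum(axis=0) <= 0).any():
            raise FormatError(f"PFM {self.id}: column with zero total count")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column-normalised frequencies with pseudocount added."""
        colsum = self.matrix.sum(axis=0, keepdims=True)
        pc = self.pseudocount_frac * colsum / 4.0
        probs = (self.matrix + pc) / (colsum + 4 * pc)
        return probs

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        """Log2 odds versus a uniform background."""
        return np.log2(self.probabilities() / background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.matrix.argmax(axis=0))


@dataclass
class VariantRecord:
    """A single-nucleotide or indel variant; ``pos`` is 0-based."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper().replace("-", "")
        if not self.ref_allele or set(self.ref_allele) - set(DNA_ALPHABET):
            raise FormatError(f"variant {self.id}: bad ref allele {self.ref_allele!r}")
        if set(self.alt_allele) - set(DNA_ALPHABET):
            raise FormatError(f"variant {self.id}: bad alt allele {self.alt_allele!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


def to_zero_based(pos: int, one_based: bool) -> int:
    """The single 1-based -> 0-based conversion point."""
    return pos - 1 if one_based else pos


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, ambiguous: str = "N") -> dict[str, str]:
    """Read a FASTA into ``{chrom: uppercase sequence}``.

    Characters outside ``{A,C,G,T,N}`` are rejected (``ambiguous="strict"``)
    or mapped to N (default).  Duplicate headers and empty records are errors.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {record.id!r}")
        bad = set(seq) - set(DNA_ALPHABET + "N")
        if bad:
            if ambiguous == "strict":
                raise FormatError(f"record {record.id!r}: non-ACGTN characters {sorted(bad)}")
            seq = "".join(c if c in DNA_ALPHABET + "N" else "N" for c in seq)
        genome[record.id] = seq
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_sequence(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Sub-sequence at 0-based half-open coordinates; out-of-bounds is an error."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    contig = genome[chrom]
    if start < 0 or end > len(contig) or end <= start:
        raise IndexError(f"{chrom}:{start}-{end} outside contig of length {len(contig)}")
    return contig[start:end]


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> list[GenomicRegion]:
    """Read ENCODE narrowPeak (10 columns) or plain BED (>= 3 columns).

    The summit is ``start + column-10 offset`` when a valid offset is present;
    macs2's ``-1`` sentinel, and plain BED, fall back to the interval midpoint.
    Input order is preserved.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
                # narrowPeak: signalValue, pValue, qValue, summit offset
                if len(fields) >= 10:
                    score = float(fields[6]) if fields[6] != "." else score
                    offset = int(fields[9])
                else:
                    offset = -1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                regions.append(
                    GenomicRegion(chrom, start, end, score=score, name=name,
                                  strand=strand, summit=summit)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path,
              header: str | None = None) -> None:
    """Write BED6; summits are re-derivable because widths are fixed."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n")


def write_narrowpeak(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write ENCODE narrowPeak; the summit goes into column 10 as an offset."""
    with open(path, "w") as fh:
        for r in regions:
            offset = (r.summit - r.start) if r.summit is not None else -1
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}"
                     f"\t{r.score:g}\t-1\t-1\t{offset}\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str | Path) -> list[MotifPFM]:
    """Read JASPAR-format PFMs: ``>ID NAME`` headers then four A/C/G/T count rows.

    Row labels (``A [ ... ]``) are handled by Biopython's JASPAR parser; bare
    four-row blocks are accepted as an unlabelled fallback in A,C,G,T order.
    """
    text = Path(path).read_text()
    try:
        with _stdio.StringIO(text) as fh:
            parsed = list(bio_motifs.parse(fh, "jaspar"))
        out = []
        for m in parsed:
            mat = np.array([m.counts[b] for b in DNA_ALPHABET], dtype=float)
            out.append(MotifPFM(id=m.matrix_id or m.name, name=m.name or m.matrix_id, matrix=mat))
        if out:
            return out
    except Exception:
        pass
    return _read_bare_pfm(text, path)


def _read_bare_pfm(text: str, path: str | Path) -> list[MotifPFM]:
    out: list[MotifPFM] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, header
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"{path}: motif {header[0]} has {len(rows)} rows, expected 4")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"{path}: motif {header[0]} rows of unequal length")
        out.append(MotifPFM(id=header[0], name=header[1], matrix=np.array(rows)))
        rows = []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            toks = line[1:].split()
            if not toks:
                raise FormatError(f"{path}: empty PFM header")
            header = (toks[0], toks[1] if len(toks) > 1 else toks[0])
        else:
            if header is None:
                raise FormatError(f"{path}: counts before any header")
            toks = line.replace("[", " ").replace("]", " ").split()
            if toks and toks[0].upper() in set("ACGT"):
                toks = toks[1:]
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise FormatError(f"{path}: bad count row {line!r}") from exc
    flush()
    if not out:
        raise FormatError(f"{path}: no PFMs found")
    return out


def write_jaspar_pfm(pfms: Iterable[MotifPFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.id} {pfm.name}\n")
            for base, row in zip(DNA_ALPHABET, pfm.matrix):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# variant and whitelist tables
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, one_based: bool = False) -> list[VariantRecord]:
    """Read a TSV with header columns id, chrom, pos, ref, alt."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing variant columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        alt = "" if (not isinstance(row.alt, str)) else row.alt
        records.append(
            VariantRecord(id=str(row.id), chrom=str(row.chrom),
                          pos=to_zero_based(int(row.pos), one_based),
                          ref_allele=str(row.ref), alt_allele=alt)
        )
    return records


def read_tf_whitelist(path: str | Path) -> set[str]:
    """One TF name per line; empty set means 'no filtering'."""
    names = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.add(line.upper())
    return names


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_bedgraph(track: Mapping[tuple[str, int], float], path: str | Path,
                   header: str | None = None) -> None:
    """Write per-base values as 4-column bedGraph, sorted by (chrom, start)."""
    keys = list(track.keys())
    if len(set(keys)) != len(keys):
        raise FormatError("duplicate positions in track")
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for chrom, pos in sorted(keys):
            if pos < 0:
                raise FormatError(f"negative position {chrom}:{pos}")
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{track[(chrom, pos)]:.6g}\n")


def read_bedgraph(path: str | Path) -> dict[tuple[str, int], float]:
    track: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            start, end = int(start), int(end)
            for pos in range(start, end):
                if (chrom, pos) in track:
                    raise FormatError(f"{path}:{lineno}: overlapping duplicate position")
                track[(chrom, pos)] = float(value)
    return track
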
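"""Genomic intervals, gene models, peaks and the flat-file formats that carry them.

All coordinates are 0-based, half-open (BED convention) throughout the
package.  knownGene-style ``txStart``/``txEnd`` columns are already 0-based
half-open; GTF coordinates (1-based, closed) are converted on input.  The
transcription start site (TSS) of a minus-strand transcript is ``end - 1``,
the last base of the half-open interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """A strand-aware transcript; the TSS is derived from the strand."""

    id: str
    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"transcript {self.id} needs a +/- strand")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


class GeneAnnotation:
    """Transcripts indexed by chromosome, sorted by TSS position."""

    def __init__(
        self,
        transcripts: Iterable[Transcript],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})
        self.by_chrom: dict[str, list[Transcript]] = {}
        self.by_id: dict[str, Transcript] = {}
        for t in transcripts:
            size = self.chrom_sizes.get(t.chrom)
            if size is not None and t.interval.end > size:
                raise ValueError(
                    f"transcript {t.id} extends past end of {t.chrom} ({size} bp)"
                )
            self.by_chrom.setdefault(t.chrom, []).append(t)
            self.by_id[t.id] = t
        for chrom in self.by_chrom:
            self.by_chrom[chrom].sort(key=lambda t: (t.tss, t.id))

    def __len__(self) -> int:
        return len(self.by_id)

    def __iter__(self):
        for chrom in sorted(self.by_chrom):
            yield from self.by_chrom[chrom]

    def transcripts(self) -> list[Transcript]:
        return list(self)

    def chrom_size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome size for {chrom!r}") from None


@dataclass(frozen=True)
class Peak:
    """An open-chromatin / ChIP-seq peak, optionally with a summit offset."""

    interval: GenomicInterval
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        so = self.summit_offset
        if so is not None and so != -1 and not (0 <= so < len(self.interval)):
            raise ValueError(
                f"summit offset {so} outside peak of length {len(self.interval)}"
            )


# ---------------------------------------------------------------------------
# readers


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_gene_models(
    path: str | Path,
    format: str = "knownGene",
    chrom_sizes: Mapping[str, int] | None = None,
) -> GeneAnnotation:
    """Read gene models from a knownGene-style tab file, BED12 or minimal GTF.

    knownGene columns used: name, chrom, strand, txStart, txEnd (0-based
    half-open).  BED12: chrom, start, end, name, score, strand.  GTF: only
    ``transcript`` features, with ``gene_id``/``transcript_id`` attributes;
    1-based closed coordinates are converted.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "knownGene":
                    if len(fields) < 5:
                        raise ValueError("need >= 5 tab-separated columns")
                    name, chrom, strand, s, e = fields[:5]
                    symbol = fields[10] if len(fields) > 10 and fields[10] else name
                    iv = GenomicInterval(chrom, int(s), int(e), strand)
                elif format == "bed12":
                    if len(fields) < 6:
                        raise ValueError("BED12 needs >= 6 columns")
                    chrom, s, e, name, _score, strand = fields[:6]
                    symbol = name
                    iv = GenomicInterval(chrom, int(s), int(e), strand)
                elif format == "gtf":
                    if len(fields) < 9:
                        raise ValueError("GTF needs 9 columns")
                    if fields[2] != "transcript":
                        continue
                    chrom, strand = fields[0], fields[6]
                    attrs = _parse_gtf_attrs(fields[8])
                    name = attrs.get("transcript_id")
                    if name is None:
                        raise ValueError("missing transcript_id attribute")
                    symbol = attrs.get("gene_name", attrs.get("gene_id", name))
                    iv = GenomicInterval(chrom, int(fields[3]) - 1, int(fields[4]), strand)
                else:
                    raise ValueError(f"unknown gene-model format {format!r}")
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from None
            transcripts.append(Transcript(name, symbol, iv))
    return GeneAnnotation(transcripts, chrom_sizes)


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_canonical_ids(path: str | Path, id_column: int = 4) -> set[str]:
    """Read a knownCanonical-style file; column 5 holds the transcript id.

    Single-column files (one id per line) are accepted too.
    """
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            ids.add(fields[id_column] if len(fields) > id_column else fields[0])
    return ids


def select_canonical(annotation: GeneAnnotation, canonical_ids: set[str]) -> GeneAnnotation:
    """Keep only the listed representative transcripts.

    Unknown ids are ignored with a warning; an empty intersection is an error
    because no genes would remain to analyse.
    """
    known = set(annotation.by_id)
    missing = set(canonical_ids) - known
    if missing:
        log.warning("%d canonical ids not present in the annotation", len(missing))
    keep = known & set(canonical_ids)
    if not keep:
        raise ValueError("no canonical transcripts found in the annotation")
    return GeneAnnotation(
        (annotation.by_id[i] for i in keep), annotation.chrom_sizes
    )


def promoter_region(
    t: Transcript,
    up: int = 5000,
    down: int = 5000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Promoter as ``[tss - up, tss + down)`` clipped to the chromosome.

    ``up``/``down`` are in bp along the genome axis (symmetric defaults make
    strand irrelevant); both zero is a degenerate empty window and an error.
    """
    if up == 0 and down == 0:
        raise ValueError("promoter window of width 0")
    start = max(0, t.tss - up)
    end = t.tss + down
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[t.chrom])
    return GenomicInterval(t.chrom, start, end, t.strand)


def read_peaks(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read narrowPeak (10 col), broadPeak (9 col) or plain BED peaks."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
                if s >= e:
                    raise ValueError(f"start {s} >= end {e}")
                strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
                iv = GenomicInterval(chrom, s, e, strand)
                score = float(fields[6]) if format in ("narrowPeak", "broadPeak") and len(fields) > 6 else (
                    float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else None
                )
                summit = None
                if format == "narrowPeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak needs 10 columns")
                    summit = int(fields[9])
                    if summit == -1:
                        summit = None
                elif format == "broadPeak":
                    if len(fields) < 9:
                        raise ValueError("broadPeak needs 9 columns")
                elif format != "bed":
                    raise ValueError(f"unknown peak format {format!r}")
                peaks.append(Peak(iv, score=score, summit_offset=summit))
            except (ValueError, IndexError) as exc:
                raise _parse_error(path, lineno, str(exc)) from None
    return peaks


def central_window(p: Peak, width: int = 50) -> GenomicInterval:
    """Central ``width``-bp window of a peak (the whole peak when shorter).

    The centre is ``floor((start + end) / 2)``; the window is
    ``[centre - width//2, centre + width - width//2)`` clipped to the peak, so
    its length is exactly ``min(width, len(peak))``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    iv = p.interval
    if len(iv) <= width:
        return iv
    center = (iv.start + iv.end) // 2
    start = center - width // 2
    end = start + width
    if start < iv.start:
        start, end = iv.start, iv.start + width
    elif end > iv.end:
        start, end = iv.end - width, iv.end
    return GenomicInterval(iv.chrom, start, end, iv.strand)


# ---------------------------------------------------------------------------
# writers


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in records:
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


def write_peaks(peaks: Sequence[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    """Write peaks back out in narrowPeak/broadPeak/BED dialect."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            score = p.score if p.score is not None else 0.0
            strand = iv.strand if iv.strand in ("+", "-") else "."
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t{int(score)}\t{strand}"
            if format == "narrowPeak":
                summit = p.summit_offset if p.summit_offset is not None else -1
                fh.write(f"{base}\t{score:g}\t-1\t-1\t{summit}\n")
            elif format == "broadPeak":
                fh.write(f"{base}\t{score:g}\t-1\t-1\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t{score:g}\t{strand}\n")


def write_gene_models(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write transcripts as a knownGene-style tab file (name..txEnd + symbol)."""
    with open(path, "w") as fh:
        for t in annotation:
            iv = t.interval
            fh.write(
                "\t".join(
                    [
                        t.id, iv.chrom, iv.strand, str(iv.start), str(iv.end),
                        str(iv.start), str(iv.end), "1", str(iv.start) + ",",
                        str(iv.end) + ",", t.symbol,
                    ]
                )
                + "\n"
            )
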
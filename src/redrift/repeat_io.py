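"""Readers and writers for the plain-text formats the pipeline touches.

Supported inputs: repeatMasker ``.out`` (UCSC dialect, 1-based inclusive
coordinates converted to 0-based half-open), BED6+2 repeat annotations
(columns 7-8 = family, subfamily), BED3/BED6 aligned-read intervals,
two-column ``chrom.sizes``. Output: 4-column bedGraph. SAM is supported only
through a thin reducer that keeps (chrom, pos, pos + aligned length) of
mapped primary alignments; BAM/CRAM are out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .intervals import (
    FAMILIES,
    AlignedRead,
    GenomicInterval,
    ReadTable,
    RepeatCopy,
)

log = logging.getLogger(__name__)

#: Editable mapping from repeatMasker repClass/repFamily labels to the closed
#: family vocabulary. Matched case-insensitively; the repFamily component is
#: tried first, then the repClass. Mouse B1/B2/B4 come straight from
#: repFamily; no Alu→B1 aliasing is assumed.
DEFAULT_FAMILY_MAP: dict[str, str] = {
    "erv1": "ERV1",
    "ervk": "ERVK",
    "ervl": "ERVL",
    "ervl-malr": "ERVL-MaLR",
    "malr": "ERVL-MaLR",
    "l1": "LINE1",
    "line1": "LINE1",
    "b1": "SINE-B1",
    "sine-b1": "SINE-B1",
    "b2": "SINE-B2",
    "sine-b2": "SINE-B2",
    "b4": "SINE-B4",
    "sine-b4": "SINE-B4",
}


class RepeatAnnotation(NamedTuple):
    copies: list[RepeatCopy]
    n_rejected: int


class AlignmentInput(NamedTuple):
    reads: ReadTable
    n_skipped: int


def map_family(label: str, family_map: Mapping[str, str] | None = None) -> str:
    """Map a repClass/repFamily label into the closed vocabulary.

    Unknown labels fall back to ``"other"`` with a logged warning.
    """
    fmap = DEFAULT_FAMILY_MAP if family_map is None else family_map
    key = label.strip().lower()
    if key in fmap:
        return fmap[key]
    if label in FAMILIES:
        return label
    log.warning("unknown repeat family label %r mapped to 'other'", label)
    return "other"


def read_repeat_annotation(
    path: str | Path,
    format: str = "rmsk_out",
    family_map: Mapping[str, str] | None = None,
) -> RepeatAnnotation:
    """Read a repeat annotation as a list of :class:`RepeatCopy`.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"rmsk_out"`` for repeatMasker ``.out`` (the 3-line header variant is
        tolerated; coordinates are 1-based inclusive and are converted), or
        ``"bed"`` for BED6 plus columns 7-8 = family, subfamily.

    Returns
    -------
    RepeatAnnotation
        ``copies`` in file order plus the count of rejected records
        (malformed coordinates after conversion).
    """
    path = Path(path)
    if format not in ("rmsk_out", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    copies: list[RepeatCopy] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if format == "rmsk_out":
                rec = _parse_rmsk_line(line, lineno, family_map)
            else:
                rec = _parse_repeat_bed_line(line, lineno, family_map)
            if rec is None:
                continue
            if rec == "rejected":
                n_rejected += 1
                continue
            copies.append(rec)
    if n_rejected:
        log.warning("%s: rejected %d malformed repeat records", path, n_rejected)
    return RepeatAnnotation(copies, n_rejected)


def _parse_rmsk_line(line: str, lineno: int, family_map):
    fields = line.split()
    # Header lines of the .out format do not start with an integer score.
    try:
        int(fields[0])
    except (ValueError, IndexError):
        return None
    if len(fields) < 11:
        return "rejected"
    chrom = fields[4]
    try:
        start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
        end = int(fields[6])
    except ValueError:
        return "rejected"
    if start < 0 or start >= end:
        return "rejected"
    strand = "-" if fields[8] in ("C", "-") else "+"
    subfamily = fields[9]
    cls_fam = fields[10].split("/")
    label = cls_fam[1] if len(cls_fam) > 1 else cls_fam[0]
    family = map_family(label, family_map)
    return RepeatCopy(
        GenomicInterval(chrom, start, end, strand),
        family=family,
        subfamily=subfamily,
        copy_id=f"{chrom}:{start}-{end}:{subfamily}",
    )


def _parse_repeat_bed_line(line: str, lineno: int, family_map):
    fields = line.split()
    if len(fields) < 8:
        return "rejected"
    chrom, name = fields[0], fields[3]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        return "rejected"
    if start < 0 or start >= end:
        return "rejected"
    strand = fields[5] if fields[5] in ("+", "-") else "."
    family = map_family(fields[6], family_map)
    return RepeatCopy(
        GenomicInterval(chrom, start, end, strand),
        family=family,
        subfamily=fields[7],
        copy_id=name,
    )


def read_alignments(path: str | Path, sample_id: str | None = None) -> AlignmentInput:
    """Read BED3/BED6 aligned-read intervals, skipping malformed lines.

    Raises if the file contains lines but none parse.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_skipped = 0
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_lines += 1
            fields = line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError):
                n_skipped += 1
                continue
            if start < 0 or start >= end:
                n_skipped += 1
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    if n_lines and not chroms:
        raise ValueError(f"{path}: no parseable alignment lines ({n_skipped} malformed)")
    if n_skipped:
        log.warning("%s: skipped %d malformed alignment lines", path, n_skipped)
    return AlignmentInput(
        ReadTable(np.array(chroms, dtype=object), starts, ends, sample_id=sample_id),
        n_skipped,
    )


def write_bedgraph(
    bins: Sequence[GenomicInterval],
    values: Sequence[float],
    path: str | Path,
) -> None:
    """Write a 4-column bedGraph with values at 6 significant digits."""
    if len(bins) != len(values):
        raise ValueError(
            f"bins ({len(bins)}) and values ({len(values)}) differ in length"
        )
    with open(path, "w") as fh:
        for b, v in zip(bins, values):
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{float(v):.6g}\n")


def read_bedgraph(path: str | Path) -> tuple[list[GenomicInterval], np.ndarray]:
    bins: list[GenomicInterval] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            bins.append(GenomicInterval(chrom, int(start), int(end)))
            values.append(float(value))
    return bins, np.asarray(values)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes file into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_reads_bed(reads: ReadTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(reads.chroms, reads.starts, reads.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


def write_repeat_bed(copies: Iterable[RepeatCopy], path: str | Path) -> None:
    """Write RepeatCopy records as BED6+2 (family, subfamily)."""
    with open(path, "w") as fh:
        for c in copies:
            strand = c.strand if c.strand in ("+", "-") else "."
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_id}\t0\t{strand}"
                f"\t{c.family}\t{c.subfamily}\n"
            )


def sam_to_alignments(path: str | Path, sample_id: str | None = None) -> AlignmentInput:
    """Reduce a text SAM file to read intervals (mapped primary alignments).

    Thin preprocessor: keeps (reference, pos, pos + aligned reference length)
    for primary mapped records. Requires pysam (``redrift[sam]`` extra).
    """
    import pysam  # deferred: core pipeline stays dependency-light

    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    chroms, starts, ends = [], [], []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            end = rec.reference_end
            if end is None or end <= rec.reference_start:
                n_skipped += 1
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(end)
    return AlignmentInput(
        ReadTable(np.array(chroms, dtype=object), starts, ends, sample_id=sample_id),
        n_skipped,
    )
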
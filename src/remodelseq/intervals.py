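"""Genomic interval data model, BED readers/writers, overlap algebra and
TSS/gene annotation.

Coordinates are BED-style 0-based half-open throughout; the center of an
interval ``[start, end)`` is ``(start + end) // 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "overlap_peaks",
    "annotate_tss",
    "assign_nearest_gene",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic span, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    name : str, optional
        Free-text label (peak class, motif name, ...).
    score : float, optional
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap_bp


class PeakSet:
    """An ordered (chrom, start, end) collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``; duplicates are
    allowed (they are distinct peak records).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (),
                 source_label: str | None = None) -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.source_label = source_label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __repr__(self) -> str:
        lbl = f", source={self.source_label!r}" if self.source_label else ""
        return f"PeakSet({len(self)} intervals{lbl})"

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def centers(self) -> np.ndarray:
        return np.array([iv.center for iv in self.intervals], dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name if iv.name is not None else "." for iv in self.intervals],
                "score": [iv.score if iv.score is not None else 0.0 for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source_label: str | None = None) -> "PeakSet":
        ivs = []
        for row in df.itertuples(index=False):
            name = getattr(row, "name", None)
            score = getattr(row, "score", None)
            strand = getattr(row, "strand", ".")
            ivs.append(
                GenomicInterval(
                    row.chrom, int(row.start), int(row.end),
                    strand=strand if strand in _STRANDS else ".",
                    name=None if name in (None, ".") else str(name),
                    score=None if score is None else float(score),
                )
            )
        return cls(ivs, source_label=source_label)


@dataclass
class GeneAnnotation:
    """A gene with its transcription start site (TSS).

    ``tss`` is a width-1 interval lying within (or at an edge of) ``body``.
    """

    gene_id: str
    tss: GenomicInterval
    body: GenomicInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.tss.length != 1:
            raise ValueError("tss must have width 1")
        if self.tss.chrom != self.body.chrom:
            raise ValueError("tss and body on different chromosomes")
        if not (self.body.start <= self.tss.start < self.body.end):
            raise ValueError(
                f"tss of {self.gene_id} outside gene body"
            )

    @property
    def tss_pos(self) -> int:
        return self.tss.start


class BedParseError(ValueError):
    """Raised for malformed BED/BEDPE lines; message names the line number."""


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise BedParseError(f"{path}:{lineno}: non-integer {what} {token!r}") from None


def read_bed(path, dialect: str = "BED6"):
    """Read a BED3/BED6 peak file or a BEDPE fragment file.

    BED3/BED6 return a :class:`PeakSet`; BEDPE returns a
    :class:`remodelseq.signal.FragmentSet` in which each read pair is
    collapsed to a single fragment spanning the outer-most coordinates of
    the two ends.

    Raises
    ------
    BedParseError
        On malformed lines (too few columns, non-integer or inverted
        coordinates), naming the offending line number.
    """
    dialect = dialect.upper()
    if dialect not in {"BED3", "BED6", "BEDPE"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if dialect == "BEDPE":
        return _read_bedpe(path)

    need = 3 if dialect == "BED3" else 6
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {need} columns, got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            name = score = None
            strand = "."
            if dialect == "BED6":
                name = None if fields[3] == "." else fields[3]
                score = None if fields[4] == "." else float(fields[4])
                strand = fields[5] if fields[5] in _STRANDS else "."
            try:
                ivs.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(ivs, source_label=path.stem)


def _read_bedpe(path: Path):
    from .signal import FragmentSet  # deferred: signal imports this module

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: BEDPE needs >= 6 columns, got {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2 = fields[:6]
            if c1 != c2:
                raise BedParseError(
                    f"{path}:{lineno}: inter-chromosomal pair {c1}/{c2} unsupported"
                )
            s1i = _parse_int(s1, path, lineno, "start1")
            e1i = _parse_int(e1, path, lineno, "end1")
            s2i = _parse_int(s2, path, lineno, "start2")
            e2i = _parse_int(e2, path, lineno, "end2")
            lo, hi = min(s1i, s2i), max(e1i, e2i)
            if not (0 <= lo < hi):
                raise BedParseError(f"{path}:{lineno}: invalid fragment span {lo}-{hi}")
            chroms.append(c1)
            starts.append(lo)
            ends.append(hi)
    return FragmentSet(
        pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}),
        condition=path.stem,
    )


def write_bed(peaks: PeakSet, path, bed6: bool = True) -> None:
    """Write a PeakSet as sorted BED3 or BED6 (class labels go in the name)."""
    with open(path, "w") as fh:
        for iv in peaks:
            if bed6:
                score = 0.0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name if iv.name is not None else '.'}\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read genes from TSV with columns gene_id, chrom, tss, strand
    (optionally body_start, body_end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.tss)
        bs = int(getattr(row, "body_start", tss))
        be = int(getattr(row, "body_end", tss + 1))
        genes.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                tss=GenomicInterval(row.chrom, tss, tss + 1, strand=row.strand),
                body=GenomicInterval(row.chrom, bs, be, strand=row.strand),
                strand=row.strand,
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.tss.chrom for g in genes],
            "tss": [g.tss_pos for g in genes],
            "strand": [g.strand for g in genes],
            "body_start": [g.body.start for g in genes],
            "body_end": [g.body.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def _has_overlap_mask(a: PeakSet, b: PeakSet, min_overlap_bp: int) -> np.ndarray:
    """Boolean per-interval-of-a: overlaps >= min_overlap_bp bp of some b interval.

    Per chromosome: with b sorted by start and a running prefix-maximum of b
    ends, interval a overlaps some b by >= m iff among b's with
    start <= a.end - m the maximum end is >= a.start + m.
    """
    out = np.zeros(len(a), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    idx_of = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(pairs, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        starts = arr[order, 0]
        maxend = np.maximum.accumulate(arr[order, 1])
        idx_of[chrom] = (starts, maxend)
    for i, iv in enumerate(a):
        hit = idx_of.get(iv.chrom)
        if hit is None:
            continue
        starts, maxend = hit
        k = int(np.searchsorted(starts, iv.end - min_overlap_bp, side="right"))
        if k > 0 and maxend[k - 1] >= iv.start + min_overlap_bp:
            out[i] = True
    return out


def overlap_peaks(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1):
    """Venn-style interval overlap between two peak sets.

    Returns ``(shared_a, a_only, b_only, shared_b)``; an interval is shared
    iff it overlaps at least one interval of the other set by at least
    ``min_overlap_bp`` bp, and each interval is counted once regardless of
    how many partners it has.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    mask_a = _has_overlap_mask(a, b, min_overlap_bp)
    mask_b = _has_overlap_mask(b, a, min_overlap_bp)
    shared_a = PeakSet([iv for iv, m in zip(a, mask_a) if m], source_label=a.source_label)
    a_only = PeakSet([iv for iv, m in zip(a, mask_a) if not m], source_label=a.source_label)
    shared_b = PeakSet([iv for iv, m in zip(b, mask_b) if m], source_label=b.source_label)
    b_only = PeakSet([iv for iv, m in zip(b, mask_b) if not m], source_label=b.source_label)
    return shared_a, a_only, b_only, shared_b


def annotate_tss(peaks: PeakSet, genes: Sequence[GeneAnnotation],
                 window_bp: int = 1000) -> list[str]:
    """Label each peak ``"TSS"`` or ``"non-TSS"``.

    A peak is TSS-proximal iff its center lies within +/- ``window_bp`` of
    any annotated TSS (inclusive bounds, so a center exactly ``window_bp``
    away is still TSS).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if not genes:
        warnings.warn("empty gene list: all peaks labeled non-TSS", stacklevel=2)
        return ["non-TSS"] * len(peaks)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.tss.chrom, []).append(g.tss_pos)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}
    labels = []
    for iv in peaks:
        pos = tss_by_chrom.get(iv.chrom)
        if pos is None:
            labels.append("non-TSS")
            continue
        c = iv.center
        j = int(np.searchsorted(pos, c))
        dmin = min(
            abs(c - pos[j - 1]) if j > 0 else np.iinfo(np.int64).max,
            abs(pos[j] - c) if j < len(pos) else np.iinfo(np.int64).max,
        )
        labels.append("TSS" if dmin <= window_bp else "non-TSS")
    return labels


def assign_nearest_gene(peaks: PeakSet, genes: Sequence[GeneAnnotation],
                        max_dist_bp: int = 100_000) -> list[str | None]:
    """Assign each peak the gene whose TSS is nearest to its center.

    Returns ``None`` when the nearest same-chromosome TSS is farther than
    ``max_dist_bp``; ties are broken toward the lexicographically smaller
    gene_id.
    """
    if max_dist_bp < 0:
        raise ValueError("max_dist_bp must be >= 0")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.tss.chrom, []).append((g.tss_pos, g.gene_id))
    out: list[str | None] = []
    for iv in peaks:
        cands = by_chrom.get(iv.chrom)
        if not cands:
            out.append(None)
            continue
        c = iv.center
        dmin = min(abs(c - p) for p, _ in cands)
        if dmin > max_dist_bp:
            out.append(None)
        else:
            out.append(min(gid for p, gid in cands if abs(c - p) == dmin))
    return out
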
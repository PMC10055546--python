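"""IUPAC consensus-motif scanning and enrichment.

Degenerate consensus patterns (WGATAR, TGASTCA, ...) are scanned exactly on
both strands; the analytic per-bp match probability under an i.i.d. base
model gives the expected genomic spacing of a motif (e.g. a fully
degenerate hexamer recurs about every few hundred bp, which is why short
TF motifs vastly outnumber the TF molecules that could bind them).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, PeakSet, overlap_peaks
from .signal import FragmentSet, count_in_windows, metaplot, normalize_counts

__all__ = [
    "IUPAC_CODES",
    "MotifPattern",
    "MotifHitSet",
    "read_fasta",
    "write_fasta",
    "read_motif_table",
    "scan_iupac",
    "scan_genome",
    "expected_motif_rate",
    "build_potential_sites",
    "sample_random_regions",
    "scanning_enrichment",
    "motif_enrichment",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate IUPAC consensus with per-position allowed-base sets."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty pattern")
        for ch in self.iupac.upper():
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC letter {ch!r} in pattern {self.name}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def positions(self) -> list[frozenset[str]]:
        return [IUPAC_CODES[ch] for ch in self.iupac]

    def reverse_complement(self) -> "MotifPattern":
        rc = "".join(
            _iupac_of(frozenset(_COMPLEMENT[b] for b in IUPAC_CODES[ch]))
            for ch in reversed(self.iupac)
        )
        return MotifPattern(self.name, rc)

    def matches(self, kmer: str) -> bool:
        kmer = kmer.upper()
        return len(kmer) == len(self) and all(
            b in allowed for b, allowed in zip(kmer, self.positions)
        )


def _iupac_of(bases: frozenset[str]) -> str:
    for code, s in IUPAC_CODES.items():
        if s == bases:
            return code
    raise ValueError(f"no IUPAC code for {bases}")


@dataclass
class MotifHitSet:
    """Exact degenerate matches of one pattern, as stranded intervals in
    plus-strand coordinates."""

    hits: PeakSet
    pattern: MotifPattern
    genome_label: str = ""

    def __post_init__(self) -> None:
        k = len(self.pattern)
        for iv in self.hits:
            if iv.length != k:
                raise ValueError("hit length differs from pattern length")

    def __len__(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------- FASTA IO

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA to {name: uppercase sequence} (N-aware)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_motif_table(path) -> list[MotifPattern]:
    """Motif patterns from a 2-column TSV (name, IUPAC string)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "iupac"], comment="#")
    return [MotifPattern(str(r.name), str(r.iupac)) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------- scanning

def _match_positions(seq_codes: np.ndarray, pattern: MotifPattern) -> np.ndarray:
    """Start offsets of exact degenerate matches of pattern on the forward
    strand of an ASCII-encoded sequence. An N in the sequence matches only a
    fully degenerate (N) pattern position."""
    k = len(pattern)
    n = len(seq_codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = None
    for i, allowed in enumerate(pattern.positions):
        table = np.zeros(256, dtype=bool)
        for b in allowed:
            table[ord(b)] = True
            table[ord(b.lower())] = True
        if allowed == IUPAC_CODES["N"]:
            table[ord("N")] = table[ord("n")] = True
        col = table[seq_codes[i:n - k + 1 + i]]
        valid = col if valid is None else (valid & col)
    return np.nonzero(valid)[0].astype(np.int64)


def scan_iupac(sequence: str, pattern: MotifPattern, both_strands: bool = True,
               chrom: str = "seq") -> MotifHitSet:
    """All exact degenerate matches of an IUPAC pattern in a DNA sequence.

    Minus-strand hits (matches of the reverse-complement pattern on the
    forward sequence) are reported in plus-strand coordinates with
    strand ``-``. A palindromic pattern therefore yields two hits, one per
    strand, at the same coordinates.
    """
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    k = len(pattern)
    ivs = [
        GenomicInterval(chrom, int(p), int(p) + k, strand="+", name=pattern.name)
        for p in _match_positions(codes, pattern)
    ]
    if both_strands:
        rc = pattern.reverse_complement()
        ivs += [
            GenomicInterval(chrom, int(p), int(p) + k, strand="-", name=pattern.name)
            for p in _match_positions(codes, rc)
        ]
    return MotifHitSet(PeakSet(ivs), pattern, genome_label=chrom)


def scan_genome(genome: dict[str, str], pattern: MotifPattern,
                both_strands: bool = True) -> MotifHitSet:
    ivs: list[GenomicInterval] = []
    for chrom, seq in genome.items():
        ivs.extend(scan_iupac(seq, pattern, both_strands, chrom=chrom).hits)
    return MotifHitSet(PeakSet(ivs), pattern, genome_label="genome")


def expected_motif_rate(pattern: MotifPattern,
                        base_probs: dict[str, float] | None = None,
                        both_strands: bool = True) -> tuple[float, float]:
    """Analytic per-bp match probability and expected spacing of a motif.

    The per-strand probability is the product over pattern positions of the
    summed probabilities of the allowed bases; the both-strand rate adds the
    reverse-complement pattern's rate (a palindromic pattern counts twice,
    matching the two hits the scanner reports). Returns ``(rate_per_bp,
    expected_spacing_bp)``; a zero rate yields infinite spacing with a
    warning.
    """
    if base_probs is None:
        base_probs = {b: 0.25 for b in "ACGT"}
    total = sum(base_probs.values())
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("base probabilities must sum to 1")

    def strand_rate(p: MotifPattern) -> float:
        r = 1.0
        for allowed in p.positions:
            r *= sum(base_probs.get(b, 0.0) for b in allowed)
        return r

    rate = strand_rate(pattern)
    if both_strands:
        rate += strand_rate(pattern.reverse_complement())
    if rate == 0.0:
        warnings.warn("motif unreachable under base model: infinite spacing",
                      stacklevel=2)
        return 0.0, math.inf
    return rate, 1.0 / rate


def build_potential_sites(hits: MotifHitSet, observed_peaks: PeakSet,
                          extend_to_bp: int = 200) -> PeakSet:
    """Isolated potential-binding loci from consensus motif matches.

    Each hit is extended symmetrically about its center to ``extend_to_bp``
    bp; every locus overlapping another extended locus is removed (both
    members of any overlapping pair), and loci overlapping any observed
    ChIP peak are removed, leaving isolated motif loci free of direct
    binding signal.
    """
    if extend_to_bp < len(hits.pattern):
        raise ValueError("extend_to_bp smaller than pattern length")
    half = extend_to_bp // 2
    seen = set()
    extended = []
    for iv in hits.hits:
        c = iv.center
        s = max(0, c - half)
        key = (iv.chrom, s, s + extend_to_bp)
        if key in seen:   # both-strand palindromic hits give one locus
            continue
        seen.add(key)
        extended.append(GenomicInterval(iv.chrom, s, s + extend_to_bp,
                                        name=hits.pattern.name))
    ext = PeakSet(extended)
    # drop every member of any mutually-overlapping group
    keep = []
    ivs = ext.intervals
    for i, iv in enumerate(ivs):
        left_clash = i > 0 and ivs[i - 1].chrom == iv.chrom and ivs[i - 1].end > iv.start
        right_clash = (i + 1 < len(ivs) and ivs[i + 1].chrom == iv.chrom
                       and iv.end > ivs[i + 1].start)
        if not (left_clash or right_clash):
            keep.append(iv)
    isolated = PeakSet(keep)
    _, clear_of_peaks, _, _ = overlap_peaks(isolated, observed_peaks) \
        if len(observed_peaks) else (None, isolated, None, None)
    return clear_of_peaks


def sample_random_regions(genome_sizes: dict[str, int], n: int, width_bp: int,
                          exclude: PeakSet, seed: int,
                          genome: dict[str, str] | None = None,
                          max_tries_per_region: int = 1000) -> PeakSet:
    """Width-matched random control regions.

    Regions are sampled uniformly over the genome, rejecting any draw that
    overlaps the exclusion set, a previously accepted region, or (when
    sequences are supplied) an N base. Reproducible under ``seed``.
    """
    if n == 0:
        return PeakSet()
    total = sum(genome_sizes.values())
    excluded_bp = sum(iv.length for iv in exclude)
    if total - excluded_bp <= n * width_bp:
        raise ValueError("insufficient eligible space for requested regions")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_sizes)
    weights = np.array([genome_sizes[c] - width_bp for c in chroms], dtype=float)
    if (weights <= 0).all():
        raise ValueError("no chromosome long enough for requested width")
    weights = np.clip(weights, 0, None)
    weights /= weights.sum()
    accepted: list[GenomicInterval] = []
    for _ in range(n * max_tries_per_region):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        s = int(rng.integers(0, genome_sizes[c] - width_bp))
        cand = GenomicInterval(c, s, s + width_bp, name="random")
        if any(cand.overlaps(iv) for iv in exclude):
            continue
        if any(cand.overlaps(iv) for iv in accepted):
            continue
        if genome is not None and "N" in genome[c][s:s + width_bp]:
            continue
        accepted.append(cand)
        if len(accepted) == n:
            return PeakSet(accepted)
    raise ValueError(f"could not place {n} regions (placed {len(accepted)})")


@dataclass
class ScanningEnrichment:
    candidate_profile: np.ndarray
    control_profile: np.ndarray
    bin_centers: np.ndarray
    candidate_counts: np.ndarray
    control_counts: np.ndarray
    statistic: float
    pvalue: float


def scanning_enrichment(chip: FragmentSet, candidate: PeakSet, random_ctrl: PeakSet,
                        window_bp: int = 500, bin_bp: int = 25,
                        count_halfwidth_bp: int = 100) -> ScanningEnrichment:
    """ChIP signal at motif-containing candidate loci vs random controls.

    Returns mean metaplot profiles (half-width ``window_bp``, for display)
    for both locus sets and a two-sided Mann-Whitney U test on per-locus
    normalized counts in a narrow ``count_halfwidth_bp`` core window.
    The core window is deliberately no wider than half the minimum locus
    spacing, so per-locus counts are independent and signal from excluded
    (bound-peak) regions cannot leak into the test; binding-level signal at
    isolated motif loci exceeding the random baseline is the footprint of
    motif scanning.
    """
    if len(candidate) == 0 or len(random_ctrl) == 0:
        raise ValueError("both locus sets must be non-empty")
    _, prof_c = metaplot(chip, candidate, window_bp, bin_bp, mode="fragment")
    sm, prof_r = metaplot(chip, random_ctrl, window_bp, bin_bp, mode="fragment")
    counts_c = normalize_counts(
        count_in_windows(chip, candidate, count_halfwidth_bp), chip.library_size)
    counts_r = normalize_counts(
        count_in_windows(chip, random_ctrl, count_halfwidth_bp), chip.library_size)
    if counts_c.max(initial=0) == 0 and counts_r.max(initial=0) == 0:
        warnings.warn("all-zero window counts: scanning enrichment undefined",
                      stacklevel=2)
        u, p = float("nan"), 1.0
    else:
        u, p = stats.mannwhitneyu(counts_c, counts_r, alternative="two-sided")
    return ScanningEnrichment(prof_c, prof_r, sm.bin_centers(), counts_c, counts_r,
                              float(u), float(p))


def _has_hit(seq: str, pattern: MotifPattern) -> bool:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if len(_match_positions(codes, pattern)):
        return True
    return bool(len(_match_positions(codes, pattern.reverse_complement())))


def motif_enrichment(peaks: PeakSet, patterns: list[MotifPattern],
                     genome: dict[str, str], background: PeakSet) -> pd.DataFrame:
    """Known-motif enrichment in a peak set versus width-matched background.

    Per pattern, a Fisher exact test on the 2x2 table of regions with /
    without at least one (both-strand) hit, BH-corrected across patterns.
    A pattern absent from both sets gets odds ratio NA and p = 1.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")

    def hit_count(ps: PeakSet, pat: MotifPattern) -> int:
        return sum(
            _has_hit(genome[iv.chrom][iv.start:iv.end], pat) for iv in ps
        )

    rows = []
    for pat in patterns:
        hp = hit_count(peaks, pat)
        hb = hit_count(background, pat)
        mp, mb = len(peaks) - hp, len(background) - hb
        if hp == 0 and hb == 0:
            orat, p = float("nan"), 1.0
        else:
            orat, p = stats.fisher_exact([[hp, mp], [hb, mb]])
        rows.append((pat.name, pat.iupac, hp, len(peaks), hb, len(background), orat, p))
    df = pd.DataFrame(rows, columns=["motif", "iupac", "peaks_with_hit", "n_peaks",
                                     "background_with_hit", "n_background",
                                     "odds_ratio", "pvalue"])
    df["fdr"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    return df
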
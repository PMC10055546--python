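"""Ground-truth synthetic data generator.

Emulates the data structure of a TF-induction / remodeler-knockdown
experiment on a small random genome: loci are planted in three archetypes —

* ``newly_accessible`` — closed at time 0, opened by the induced factor:
  ATAC signal rises sharply; MNase dyads form a phased array flanking a
  nucleosome-depleted region over the motif, with higher array occupancy
  under remodeler knockdown (kd);
* ``constitutively_accessible`` — open before and after induction;
* ``constitutively_inaccessible`` — a nucleosome sits over the motif and
  the locus stays closed in control cells; under kd the ATAC rate rises
  (aberrant opening) and the programmed dyad is displaced off the motif.

ATAC counts are negative-binomial across replicates (gamma-Poisson),
MNase fragments are mono-nucleosome sized (Normal(147, 8), clipped) with
midpoints jittered around programmed dyads, and ChIP fragments pile up at
bound motifs with a weak motif-proportional "scanning" background.

Fragment sets carry ``library_size`` of a genome-wide experiment (default
5e7 for ATAC) while holding only the fragments on the simulated
chromosomes: the toy genome is modeled as a slice of a full library, which
places normalized counts (fragments per 1e7) in the realistic regime for
the 30-normalized-read classification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, GenomicInterval, PeakSet
from .motifs import MotifPattern, IUPAC_CODES
from .signal import FragmentSet

__all__ = [
    "LocusArchetype",
    "TruthTable",
    "default_archetypes",
    "generate_genome",
    "plant_loci",
    "simulate_atac",
    "simulate_mnase",
    "simulate_chip",
    "simulate_expression",
    "simulate_null_counts",
]

GATA_MOTIF = MotifPattern("GATA", "WGATAR")

ATAC_LIBRARY_SIZE = 50_000_000
MNASE_LIBRARY_SIZE = 20_000_000
CHIP_LIBRARY_SIZE = 20_000_000


@dataclass(frozen=True)
class LocusArchetype:
    """Ground-truth locus program: chromatin geometry plus ATAC/expression
    rates per condition and timepoint.

    ``atac_rate_*`` are mean fragments per locus per replicate (raw, at the
    default library slice); ``atac_kd_t12_multiplier`` scales the t12 rate
    under remodeler knockdown. Array occupancies are the per-dyad sampling
    fractions of the flanking nucleosomes; ``dyad_offset_over_motif_bp``
    positions the motif-covering nucleosome (inaccessible archetype) and
    ``dyad_kd_displacement_bp`` shifts it under knockdown.
    """

    name: str
    class_truth: str
    motif: MotifPattern = GATA_MOTIF
    ndr_halfwidth_bp: int = 150
    array_spacing_bp: int = 190
    array_occupancy_control: float = 0.6
    array_occupancy_kd: float = 0.6
    dyad_offset_over_motif_bp: int = 0
    dyad_kd_displacement_bp: int = 0
    atac_rate_t0: float = 10.0
    atac_rate_t12: float = 10.0
    atac_kd_t12_multiplier: float = 1.0
    dispersion: float = 0.05
    expression_log2fc: float = 0.0
    direction: str = "unchanged"

    def __post_init__(self) -> None:
        if not (0 <= self.array_occupancy_control <= 1
                and 0 <= self.array_occupancy_kd <= 1):
            raise ValueError("occupancies must lie in [0, 1]")
        if min(self.atac_rate_t0, self.atac_rate_t12) < 0:
            raise ValueError("ATAC rates must be >= 0")
        if self.array_spacing_bp <= 170:
            raise ValueError("array spacing must exceed mono-nucleosomal lengths")


def default_archetypes(motif: MotifPattern = GATA_MOTIF) -> list[LocusArchetype]:
    """The three locus programs at the generator's default effect sizes."""
    return [
        LocusArchetype(
            name="newly_accessible", class_truth="newly_accessible", motif=motif,
            atac_rate_t0=20.0, atac_rate_t12=300.0, atac_kd_t12_multiplier=3.0,
            array_occupancy_control=0.5, array_occupancy_kd=0.85,
            expression_log2fc=1.5, direction="increased",
        ),
        LocusArchetype(
            name="constitutively_accessible", class_truth="constitutively_accessible",
            motif=motif,
            atac_rate_t0=250.0, atac_rate_t12=260.0, atac_kd_t12_multiplier=0.35,
            array_occupancy_control=0.6, array_occupancy_kd=0.6,
            expression_log2fc=-1.2, direction="decreased",
        ),
        LocusArchetype(
            name="constitutively_inaccessible",
            class_truth="constitutively_inaccessible", motif=motif,
            atac_rate_t0=5.0, atac_rate_t12=10.0, atac_kd_t12_multiplier=4.0,
            dyad_offset_over_motif_bp=0, dyad_kd_displacement_bp=90,
            array_occupancy_control=0.0, array_occupancy_kd=0.0,
            expression_log2fc=1.2, direction="increased",
        ),
    ]


@dataclass
class TruthTable:
    """One row per planted locus: coordinates, archetype, motif, linked gene
    and programmed dyad positions per condition ("pos:occupancy;..." strings).
    """

    df: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __len__(self) -> int:
        return len(self.df)

    def peaks(self, halfwidth_bp: int = 250) -> PeakSet:
        """TF peak set over the planted loci (centered intervals)."""
        return PeakSet(
            [GenomicInterval(r.chrom, r.center - halfwidth_bp, r.center + halfwidth_bp,
                             name=r.locus_id)
             for r in self.df.itertuples(index=False)]
        )

    def genes(self) -> list[GeneAnnotation]:
        out = []
        for r in self.df.itertuples(index=False):
            tss = GenomicInterval(r.chrom, r.gene_tss, r.gene_tss + 1, strand="+")
            body = GenomicInterval(r.chrom, r.gene_tss, r.gene_tss + 500, strand="+")
            out.append(GeneAnnotation(r.gene_id, tss, body, "+"))
        return out

    def subset(self, class_truth: str) -> "TruthTable":
        sub = self.df[self.df["class_truth"] == class_truth].reset_index(drop=True)
        return TruthTable(sub, self.chrom_sizes)

    def dyads(self, condition: str, timepoint: str) -> list[list[tuple[int, float]]]:
        col = "dyads_t0" if timepoint == "t0" else f"dyads_{condition}_t12"
        out = []
        for s in self.df[col]:
            if not s:
                out.append([])
            else:
                out.append([(int(tok.split(":")[0]), float(tok.split(":")[1]))
                            for tok in s.split(";")])
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"#chrom_size\t{chrom}\t{size}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        import io

        sizes = {}
        body: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#chrom_size"):
                    _, chrom, size = line.rstrip("\n").split("\t")
                    sizes[chrom] = int(size)
                else:
                    body.append(line)
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t",
                         dtype={"chrom": str, "gene_id": str, "locus_id": str},
                         keep_default_na=False)
        return cls(df, sizes)


def generate_genome(n_chroms: int = 2, chrom_len_bp: int = 2_500_000,
                    gc: float = 0.41, seed: int = 0) -> dict[str, str]:
    """i.i.d. random genome at the stated GC content (default 0.41, the
    human genome-wide value)."""
    if not (0 <= gc <= 1):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(n_chroms):
        draw = rng.choice(alphabet, size=chrom_len_bp, p=p)
        genome[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return genome


def _programmed_dyads(arch: LocusArchetype, center: int) -> dict[str, list[tuple[int, float]]]:
    s = arch.array_spacing_bp
    flanks_c = [(center + k * s, arch.array_occupancy_control) for k in (-2, -1, 1, 2)]
    flanks_kd = [(center + k * s, arch.array_occupancy_kd) for k in (-2, -1, 1, 2)]
    if arch.class_truth == "newly_accessible":
        return {
            "t0": [(center, 0.8)] + [(p, 0.4) for p, _ in flanks_c],
            "control_t12": flanks_c,
            "kd_t12": flanks_kd,
        }
    if arch.class_truth == "constitutively_accessible":
        return {"t0": flanks_c, "control_t12": flanks_c, "kd_t12": flanks_kd}
    # constitutively inaccessible: a nucleosome over the motif
    on_motif = [(center + arch.dyad_offset_over_motif_bp, 0.9)]
    displaced = [(center + arch.dyad_offset_over_motif_bp
                  + arch.dyad_kd_displacement_bp, 0.9)]
    return {"t0": on_motif, "control_t12": on_motif, "kd_t12": displaced}


def _dyad_str(dyads: list[tuple[int, float]]) -> str:
    return ";".join(f"{p}:{occ:g}" for p, occ in dyads if occ > 0)


def _realize_motif(pattern: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC_CODES[ch])[int(rng.integers(len(IUPAC_CODES[ch])))]
                   for ch in pattern.iupac)


def plant_loci(genome: dict[str, str], n_per_archetype: int = 300,
               archetypes: list[LocusArchetype] | None = None,
               min_separation_bp: int = 5000,
               seed: int = 0) -> tuple[dict[str, str], TruthTable]:
    """Write motif instances into the genome at archetype loci and record
    the ground truth.

    Loci are placed on a shuffled grid of candidate positions spaced
    ``min_separation_bp`` apart (margin ``min_separation_bp`` from
    chromosome ends), so pairwise separations are guaranteed. Each locus
    gets a linked gene whose TSS sits 1.5 kb downstream of the locus
    center.
    """
    archetypes = archetypes if archetypes is not None else default_archetypes()
    rng = np.random.default_rng(seed)
    sizes = {c: len(s) for c, s in genome.items()}
    candidates = []
    for chrom in sorted(genome):
        L = sizes[chrom]
        for pos in range(min_separation_bp, L - min_separation_bp, min_separation_bp):
            candidates.append((chrom, pos))
    n_total = n_per_archetype * len(archetypes)
    if n_total == 0:
        return genome, TruthTable(
            pd.DataFrame(columns=_TRUTH_COLUMNS), sizes)
    if len(candidates) < n_total:
        raise ValueError(
            f"genome too small: {len(candidates)} candidate loci < {n_total}"
        )
    order = rng.permutation(len(candidates))[:n_total]
    chosen = [candidates[i] for i in sorted(order)]
    labels = np.repeat(np.arange(len(archetypes)), n_per_archetype)
    labels = labels[rng.permutation(n_total)]

    edit = {c: bytearray(s, "ascii") for c, s in genome.items()}
    rows = []
    for i, ((chrom, center), ai) in enumerate(zip(chosen, labels)):
        arch = archetypes[ai]
        k = len(arch.motif)
        mstart = center - k // 2
        instance = _realize_motif(arch.motif, rng)
        edit[chrom][mstart:mstart + k] = instance.encode("ascii")
        dyads = _programmed_dyads(arch, center)
        locus_id = f"locus{i:04d}"
        rows.append(
            {
                "locus_id": locus_id,
                "chrom": chrom,
                "center": center,
                "start": center - 1000,
                "end": center + 1000,
                "archetype": arch.name,
                "class_truth": arch.class_truth,
                "direction": arch.direction,
                "motif_name": arch.motif.name,
                "motif_iupac": arch.motif.iupac,
                "motif_start": mstart,
                "motif_end": mstart + k,
                "gene_id": f"gene{i:04d}",
                # decreased-direction loci model promoter-proximal peaks
                "gene_tss": center + (300 if arch.direction == "decreased" else 1500),
                "gene_log2fc_true": arch.expression_log2fc,
                "dyads_t0": _dyad_str(dyads["t0"]),
                "dyads_control_t12": _dyad_str(dyads["control_t12"]),
                "dyads_kd_t12": _dyad_str(dyads["kd_t12"]),
            }
        )
    new_genome = {c: b.decode("ascii") for c, b in edit.items()}
    return new_genome, TruthTable(pd.DataFrame(rows), sizes)


_TRUTH_COLUMNS = [
    "locus_id", "chrom", "center", "start", "end", "archetype", "class_truth",
    "direction", "motif_name", "motif_iupac", "motif_start", "motif_end",
    "gene_id", "gene_tss",
    "gene_log2fc_true", "dyads_t0", "dyads_control_t12", "dyads_kd_t12",
]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with var = m + dispersion*m^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _archetype_lookup(truth: TruthTable,
                      archetypes: list[LocusArchetype]) -> list[LocusArchetype]:
    by_name = {a.name: a for a in archetypes}
    missing = set(truth.df["archetype"]) - set(by_name)
    if missing:
        raise ValueError(f"truth references unknown archetypes {sorted(missing)}")
    return [by_name[a] for a in truth.df["archetype"]]


def simulate_atac(truth: TruthTable, condition: str = "control",
                  timepoint: str = "t12", replicates: int = 3,
                  archetypes: list[LocusArchetype] | None = None,
                  dispersion: float | None = None,
                  background_density: float = 0.015,
                  library_size: int = ATAC_LIBRARY_SIZE,
                  insert_range: tuple[int, int] = (60, 120),
                  seed: int = 0) -> list[FragmentSet]:
    """Per-replicate ATAC fragment sets.

    Per-locus fragment counts are negative-binomial with the archetype's
    rate for the timepoint (kd multiplies the t12 rate); fragments are
    short inserts (60-120 bp) with midpoints uniform over the locus NDR.
    A uniform background of ``background_density`` fragments/bp/replicate
    covers the rest of the genome.
    """
    if condition not in {"control", "kd"}:
        raise ValueError(f"unknown condition {condition!r}")
    if timepoint not in {"t0", "t12"}:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    archetypes = archetypes if archetypes is not None else default_archetypes()
    archs = _archetype_lookup(truth, archetypes)
    rng = np.random.default_rng(seed)
    rates = np.array([
        (a.atac_rate_t0 if timepoint == "t0" else
         a.atac_rate_t12 * (a.atac_kd_t12_multiplier if condition == "kd" else 1.0))
        for a in archs
    ])
    ndr = np.array([a.ndr_halfwidth_bp for a in archs])
    centers = truth.df["center"].to_numpy()
    chroms = truth.df["chrom"].to_numpy()

    out = []
    for rep in range(replicates):
        frag_chrom: list[np.ndarray] = []
        frag_start: list[np.ndarray] = []
        frag_end: list[np.ndarray] = []
        counts = _nb_counts(
            rng, rates,
            dispersion if dispersion is not None
            else (archs[0].dispersion if archs else 0.05))
        for i in range(len(truth)):
            n = int(counts[i])
            if n == 0:
                continue
            mids = centers[i] + rng.integers(-ndr[i], ndr[i] + 1, size=n)
            lens = rng.integers(insert_range[0], insert_range[1] + 1, size=n)
            starts = mids - lens // 2
            frag_chrom.append(np.repeat(chroms[i], n))
            frag_start.append(starts)
            frag_end.append(starts + lens)
        for chrom in sorted(truth.chrom_sizes):
            L = truth.chrom_sizes[chrom]
            nbg = rng.poisson(background_density * L)
            lens = rng.integers(insert_range[0], insert_range[1] + 1, size=nbg)
            starts = rng.integers(0, L - insert_range[1], size=nbg)
            frag_chrom.append(np.repeat(chrom, nbg))
            frag_start.append(starts)
            frag_end.append(starts + lens)
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(frag_chrom) if frag_chrom else [],
                "start": np.concatenate(frag_start) if frag_start else [],
                "end": np.concatenate(frag_end) if frag_end else [],
            }
        )
        df["start"] = df["start"].clip(lower=0)
        out.append(FragmentSet(df, library_size=library_size,
                               condition=f"{condition}_{timepoint}",
                               replicate=f"rep{rep + 1}"))
    return out


def _mnase_lengths(rng: np.random.Generator, n: int, mean: float = 147.0,
                   sd: float = 8.0, clip: tuple[int, int] = (100, 200)) -> np.ndarray:
    lens = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.clip(lens, clip[0], clip[1])


def simulate_mnase(truth: TruthTable, condition: str = "control",
                   timepoint: str = "t12", frags_per_dyad: float = 40.0,
                   jitter_sd_bp: float = 20.0, background_density: float = 0.001,
                   library_size: int = MNASE_LIBRARY_SIZE,
                   seed: int = 0) -> FragmentSet:
    """Capture-MNase-like fragments around the programmed dyads.

    Per dyad, Poisson(``frags_per_dyad`` x occupancy) fragments with
    lengths Normal(147, 8) clipped to [100, 200] and midpoints at the dyad
    plus Normal(0, ``jitter_sd_bp``); a sparse uniform background is added.
    """
    if jitter_sd_bp < 0:
        raise ValueError("jitter_sd_bp must be >= 0")
    rng = np.random.default_rng(seed)
    dyads = truth.dyads(condition, timepoint)
    chroms = truth.df["chrom"].to_numpy()
    frag_chrom: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    frag_end: list[np.ndarray] = []
    for i, locus_dyads in enumerate(dyads):
        for pos, occ in locus_dyads:
            n = int(rng.poisson(frags_per_dyad * occ))
            if n == 0:
                continue
            if jitter_sd_bp > 0:
                mids = np.rint(pos + rng.normal(0.0, jitter_sd_bp, size=n)).astype(np.int64)
            else:
                mids = np.full(n, pos, dtype=np.int64)
            lens = _mnase_lengths(rng, n)
            starts = mids - lens // 2
            frag_chrom.append(np.repeat(chroms[i], n))
            frag_start.append(starts)
            frag_end.append(starts + lens)
    for chrom in sorted(truth.chrom_sizes):
        L = truth.chrom_sizes[chrom]
        nbg = rng.poisson(background_density * L)
        if nbg == 0:
            continue
        lens = _mnase_lengths(rng, nbg)
        starts = rng.integers(0, L - 200, size=nbg)
        frag_chrom.append(np.repeat(chrom, nbg))
        frag_start.append(starts)
        frag_end.append(starts + lens)
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(frag_chrom) if frag_chrom else [],
            "start": np.concatenate(frag_start) if frag_start else [],
            "end": np.concatenate(frag_end) if frag_end else [],
        }
    )
    df["start"] = df["start"].clip(lower=0)
    return FragmentSet(df, library_size=library_size,
                       condition=f"{condition}_{timepoint}_mnase")


DEFAULT_BOUND_FRACTION = {
    "newly_accessible": 0.6,
    "constitutively_accessible": 0.6,
    "constitutively_inaccessible": 0.1,
}


def simulate_chip(truth: TruthTable, tf: str = "TF",
                  motif_hits: PeakSet | None = None,
                  bound_fraction: dict[str, float] | float = None,
                  frags_per_bound: float = 80.0, scanning_weight: float = 3.0,
                  background_density: float = 0.002,
                  fragment_length: tuple[int, int] = (150, 250),
                  library_size: int = CHIP_LIBRARY_SIZE,
                  seed: int = 0) -> tuple[FragmentSet, PeakSet]:
    """ChIP fragments: strong pileups at bound loci, weak motif-proportional
    scanning signal elsewhere, uniform background.

    A per-class fraction of truth loci is bound (strong peaks; returned as
    the true peak BED). Every unbound motif site — the unbound truth loci,
    plus all genome-wide matches in ``motif_hits`` if given — receives
    Poisson(``scanning_weight``) fragments, the signature of consensus
    motif scanning.
    """
    if scanning_weight < 0:
        raise ValueError("scanning_weight must be >= 0")
    if bound_fraction is None:
        bound_fraction = DEFAULT_BOUND_FRACTION
    if isinstance(bound_fraction, (int, float)):
        bound_fraction = {c: float(bound_fraction) for c in
                          set(truth.df["class_truth"])}
    rng = np.random.default_rng(seed)
    df = truth.df
    bound_mask = np.array([
        rng.random() < bound_fraction.get(c, 0.0) for c in df["class_truth"]
    ])
    motif_centers = ((df["motif_start"] + df["motif_end"]) // 2).to_numpy()
    chroms = df["chrom"].to_numpy()

    frag_chrom: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    frag_end: list[np.ndarray] = []

    def add_site(chrom: str, center: int, n: int) -> None:
        if n == 0:
            return
        mids = np.rint(center + rng.normal(0.0, 40.0, size=n)).astype(np.int64)
        lens = rng.integers(fragment_length[0], fragment_length[1] + 1, size=n)
        starts = np.clip(mids - lens // 2, 0, None)
        frag_chrom.append(np.repeat(chrom, n))
        frag_start.append(starts)
        frag_end.append(starts + lens)

    # peak intervals cover the full pileup footprint (midpoint jitter plus
    # fragment length), as a peak caller would report them
    peak_halfwidth = 300
    bound_peaks = []
    for i in np.nonzero(bound_mask)[0]:
        add_site(chroms[i], int(motif_centers[i]), int(rng.poisson(frags_per_bound)))
        bound_peaks.append(
            GenomicInterval(chroms[i], int(motif_centers[i]) - peak_halfwidth,
                            int(motif_centers[i]) + peak_halfwidth, name=tf)
        )
    peaks = PeakSet(bound_peaks, source_label=tf)

    # weak scanning signal at unbound motif sites
    if motif_hits is not None:
        from .intervals import _has_overlap_mask

        overlaps_bound = _has_overlap_mask(motif_hits, peaks, 1)
        seen: set[tuple[str, int, int]] = set()
        for iv, hit in zip(motif_hits, overlaps_bound):
            if hit:
                continue
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:  # palindromic motifs match both strands at one site
                continue
            seen.add(key)
            add_site(iv.chrom, iv.center, int(rng.poisson(scanning_weight)))
    else:
        for i in np.nonzero(~bound_mask)[0]:
            add_site(chroms[i], int(motif_centers[i]), int(rng.poisson(scanning_weight)))

    for chrom in sorted(truth.chrom_sizes):
        L = truth.chrom_sizes[chrom]
        nbg = rng.poisson(background_density * L)
        if nbg:
            lens = rng.integers(fragment_length[0], fragment_length[1] + 1, size=nbg)
            starts = rng.integers(0, L - fragment_length[1], size=nbg)
            frag_chrom.append(np.repeat(chrom, nbg))
            frag_start.append(starts)
            frag_end.append(starts + lens)

    fdf = pd.DataFrame(
        {
            "chrom": np.concatenate(frag_chrom) if frag_chrom else [],
            "start": np.concatenate(frag_start) if frag_start else [],
            "end": np.concatenate(frag_end) if frag_end else [],
        }
    )
    frags = FragmentSet(fdf, library_size=library_size, condition=f"{tf}_chip")
    return frags, peaks


def simulate_expression(truth: TruthTable,
                        coupling: dict[str, float] | None = None,
                        noise_sd: float = 0.3, seed: int = 0) -> pd.Series:
    """Gene log2 fold changes coupled to locus archetypes plus Gaussian
    noise. ``coupling`` overrides the truth-table per-archetype log2FC."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.array([
        coupling[a] if coupling is not None and a in coupling else fc
        for a, fc in zip(truth.df["archetype"], truth.df["gene_log2fc_true"])
    ], dtype=float)
    vals = base + (rng.normal(0.0, noise_sd, size=len(base)) if noise_sd > 0 else 0.0)
    return pd.Series(vals, index=pd.Index(truth.df["gene_id"], name="gene_id"),
                     name="log2fc")


def simulate_null_counts(n_peaks: int = 2000, replicates: int = 3,
                         mean: float = 100.0, dispersion: float = 0.05,
                         library_size: int = ATAC_LIBRARY_SIZE,
                         seed: int = 0):
    """Condition-permuted null: two conditions drawn from the same
    negative-binomial count distribution (no true signal). Returns
    ``(counts_a, counts_b, lib_sizes_a, lib_sizes_b)`` shaped for
    :func:`remodelseq.signal.differential_peaks`."""
    rng = np.random.default_rng(seed)
    means = np.full(n_peaks, mean)
    a = np.column_stack([_nb_counts(rng, means, dispersion) for _ in range(replicates)])
    b = np.column_stack([_nb_counts(rng, means, dispersion) for _ in range(replicates)])
    libs = np.full(replicates, library_size, dtype=np.int64)
    return a, b, libs.copy(), libs.copy()
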
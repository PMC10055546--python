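"""Named end-to-end workflows.

Two workflows mirror the two experimental arcs the package serves:

* ``run_steady_state`` — differential ATAC peaks between control and
  remodeler-knockdown cells, TSS annotation with a chi-square test against
  the whole-peak-set distribution, known-motif enrichment of differential
  peaks, and integration with gene-expression fold changes;
* ``run_reprogramming`` — three-class accessibility classification of TF
  peaks across factor induction, class-wise ATAC metaplots, MNase dyad
  profiles with control-vs-knockdown ratio matrices and phasing scores,
  and consensus-motif scanning enrichment.

Both read a YAML config, write stage-named TSV/BED/JSON outputs under the
output directory, and record seed, parameters and per-stage counts in a
manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationConfig, classify_gata3_peaks, integrate_expression
from .intervals import (GenomicInterval, PeakSet, assign_nearest_gene, annotate_tss,
                        read_bed, read_gene_table, write_bed, write_gene_table)
from .motifs import (MotifPattern, build_potential_sites, motif_enrichment,
                     read_fasta, read_motif_table, sample_random_regions,
                     scan_genome, scanning_enrichment, write_fasta)
from .nucleosomes import dyad_frequency, filter_mononucleosomal, normalize_to_reference, \
    phasing_score
from .signal import (FragmentSet, count_in_windows, differential_peaks, metaplot,
                     category_chisq)
from .simulate import (default_archetypes, generate_genome, plant_loci,
                       simulate_atac, simulate_chip, simulate_expression,
                       simulate_mnase, ATAC_LIBRARY_SIZE, MNASE_LIBRARY_SIZE,
                       CHIP_LIBRARY_SIZE)

log = logging.getLogger("remodelseq")

__all__ = ["RunConfig", "simulate_dataset", "run_steady_state", "run_reprogramming"]


@dataclass
class RunConfig:
    """Validated workflow configuration (paths + parameters)."""

    outdir: str
    seed: int = 0
    peaks: str | None = None
    genome: str | None = None
    genes: str | None = None
    expression: str | None = None
    motifs: str | None = None
    atac: dict = field(default_factory=dict)      # group -> list of BEDPE paths
    mnase: dict = field(default_factory=dict)     # label -> BEDPE path
    chip: str | None = None
    chip_peaks: str | None = None
    atac_library_size: int = ATAC_LIBRARY_SIZE
    mnase_library_size: int = MNASE_LIBRARY_SIZE
    chip_library_size: int = CHIP_LIBRARY_SIZE
    window_bp: int = 1000
    bin_bp: int = 25
    dyad_window_bp: int = 600
    dyad_bin_bp: int = 10
    count_halfwidth_bp: int = 200
    fdr_cutoff: float = 0.01
    fc_cutoff: float = 2.0
    scale: float = 1e7
    max_gene_dist_bp: int = 100_000
    scan_motif: str = "AP1"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def require(self, *names: str) -> None:
        """Fail before any computation if a referenced input is missing."""
        missing = []
        for name in names:
            val = getattr(self, name)
            if val is None:
                missing.append(name)
            elif isinstance(val, str) and not Path(val).exists():
                missing.append(f"{name} ({val})")
        if missing:
            raise FileNotFoundError(f"missing inputs: {', '.join(missing)}")

    def require_atac(self, *groups: str) -> None:
        for g in groups:
            paths = self.atac.get(g)
            if not paths:
                raise FileNotFoundError(f"missing atac.{g} fragment files")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing atac.{g} file {p}")


def _load_atac(cfg: RunConfig, group: str) -> list[FragmentSet]:
    out = []
    for i, p in enumerate(cfg.atac[group]):
        fs = read_bed(p, "BEDPE")
        out.append(FragmentSet(fs.fragments, library_size=cfg.atac_library_size,
                               condition=group, replicate=f"rep{i + 1}"))
    return out


def _write_manifest(outdir: Path, workflow: str, cfg: RunConfig, stages: dict) -> None:
    manifest = {
        "workflow": workflow,
        "package_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def simulate_dataset(outdir, seed: int = 0, n_per_archetype: int = 300,
                     n_chroms: int = 2, chrom_len_bp: int = 2_500_000,
                     replicates: int = 3) -> dict:
    """Generate a complete synthetic dataset on disk plus ready-to-run
    workflow configs (``steady_state.yaml``, ``reprogramming.yaml``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(seed).spawn(16)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]

    genome = generate_genome(n_chroms, chrom_len_bp, seed=seeds[0])
    genome, truth = plant_loci(genome, n_per_archetype, seed=seeds[1])
    write_fasta(genome, outdir / "genome.fa")
    truth.to_tsv(outdir / "truth.tsv")
    peaks = truth.peaks()
    write_bed(peaks, outdir / "peaks.bed")
    write_gene_table(truth.genes(), outdir / "genes.tsv")
    simulate_expression(truth, seed=seeds[2]).to_csv(outdir / "expression.tsv", sep="\t")
    with open(outdir / "motifs.tsv", "w") as fh:
        fh.write("GATA\tWGATAR\nAP1\tTGASTCA\n")

    atac_paths: dict[str, list[str]] = {}
    for group, (cond, tp), s in (
        ("control_t0", ("control", "t0"), seeds[3]),
        ("control_t12", ("control", "t12"), seeds[4]),
        ("kd_t0", ("kd", "t0"), seeds[5]),
        ("kd_t12", ("kd", "t12"), seeds[6]),
    ):
        reps = simulate_atac(truth, cond, tp, replicates=replicates, seed=s)
        atac_paths[group] = []
        for i, fs in enumerate(reps):
            p = outdir / f"atac_{group}_rep{i + 1}.bedpe"
            fs.write_bedpe(p)
            atac_paths[group].append(str(p))

    mnase_paths = {}
    for label, (cond, tp), s in (
        ("t0", ("control", "t0"), seeds[7]),
        ("control", ("control", "t12"), seeds[8]),
        ("kd", ("kd", "t12"), seeds[9]),
    ):
        fs = simulate_mnase(truth, cond, tp, seed=s)
        p = outdir / f"mnase_{label}.bedpe"
        fs.write_bedpe(p)
        mnase_paths[label] = str(p)

    # the ChIP arc scans for the AP1 consensus (sparse enough, ~1 site / 4 kb,
    # that random control regions are mostly motif-free)
    hits = scan_genome(genome, AP1_MOTIF)
    chip, chip_peaks = simulate_chip(truth, tf="TF", motif_hits=hits.hits,
                                     seed=seeds[10])
    chip.write_bedpe(outdir / "chip.bedpe")
    write_bed(chip_peaks, outdir / "chip_peaks.bed")

    common = dict(
        seed=seed, peaks=str(outdir / "peaks.bed"), genome=str(outdir / "genome.fa"),
        genes=str(outdir / "genes.tsv"), expression=str(outdir / "expression.tsv"),
        motifs=str(outdir / "motifs.tsv"), chip=str(outdir / "chip.bedpe"),
        chip_peaks=str(outdir / "chip_peaks.bed"),
    )
    steady = dict(common, outdir=str(outdir / "steady_state"),
                  atac={"control": atac_paths["control_t12"],
                        "kd": atac_paths["kd_t12"]})
    reprog = dict(common, outdir=str(outdir / "reprogramming"),
                  atac={"t0": atac_paths["control_t0"],
                        "t12": atac_paths["control_t12"],
                        "kd_t0": atac_paths["kd_t0"],
                        "kd_t12": atac_paths["kd_t12"]},
                  mnase=mnase_paths)
    with open(outdir / "steady_state.yaml", "w") as fh:
        yaml.safe_dump(steady, fh, sort_keys=True)
    with open(outdir / "reprogramming.yaml", "w") as fh:
        yaml.safe_dump(reprog, fh, sort_keys=True)
    return {"outdir": str(outdir), "n_loci": len(truth),
            "steady_state_config": str(outdir / "steady_state.yaml"),
            "reprogramming_config": str(outdir / "reprogramming.yaml")}


AP1_MOTIF = MotifPattern("AP1", "TGASTCA")


def truth_pattern(truth) -> MotifPattern:
    """The (single) motif pattern a truth table was planted with."""
    pairs = set(zip(truth.df["motif_name"], truth.df["motif_iupac"]))
    if len(pairs) != 1:
        raise ValueError("mixed-motif truth tables need an explicit pattern")
    name, iupac = pairs.pop()
    return MotifPattern(name, iupac)


def run_steady_state(cfg: RunConfig) -> dict:
    """Differential accessibility workflow (control vs knockdown)."""
    cfg.require("peaks", "genome", "genes", "expression", "motifs")
    cfg.require_atac("control", "kd")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    peaks = read_bed(cfg.peaks, "BED6")
    genome = read_fasta(cfg.genome)
    genes = read_gene_table(cfg.genes)
    expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)["log2fc"]
    patterns = read_motif_table(cfg.motifs)
    ctrl = _load_atac(cfg, "control")
    kd = _load_atac(cfg, "kd")
    stages["inputs"] = {
        "n_peaks": len(peaks),
        "control_fragments": [len(f) for f in ctrl],
        "kd_fragments": [len(f) for f in kd],
    }

    # differential peaks
    counts_c = np.column_stack(
        [count_in_windows(f, peaks, cfg.count_halfwidth_bp) for f in ctrl])
    counts_k = np.column_stack(
        [count_in_windows(f, peaks, cfg.count_halfwidth_bp) for f in kd])
    diff = differential_peaks(counts_c, counts_k,
                              [f.library_size for f in ctrl],
                              [f.library_size for f in kd],
                              fc_cutoff=cfg.fc_cutoff, fdr_cutoff=cfg.fdr_cutoff,
                              scale=cfg.scale)
    diffdir = outdir / "differential"
    diffdir.mkdir(exist_ok=True)
    diff_out = pd.concat([peaks.to_dataframe().reset_index(drop=True), diff], axis=1)
    diff_out.to_csv(diffdir / "differential_peaks.tsv", sep="\t", index=False)
    for cls in ("increased", "decreased"):
        sub = PeakSet([iv for iv, c in zip(peaks, diff["peak_class"]) if c == cls])
        write_bed(sub, diffdir / f"{cls}.bed")
    class_counts = diff["peak_class"].value_counts().to_dict()
    stages["differential"] = {"class_counts": class_counts}

    # TSS annotation + chi-square vs the whole peak set
    tssdir = outdir / "tss"
    tssdir.mkdir(exist_ok=True)
    labels = np.array(annotate_tss(peaks, genes))
    all_counts = [int((labels == "TSS").sum()), int((labels == "non-TSS").sum())]
    tss_rows = [("all", *all_counts, float("nan"), float("nan"))]
    for cls in ("increased", "decreased"):
        mask = (diff["peak_class"] == cls).to_numpy()
        obs = [int((labels[mask] == "TSS").sum()), int((labels[mask] == "non-TSS").sum())]
        if sum(obs) and min(all_counts) > 0:
            stat, p = category_chisq(obs, all_counts)
        else:
            stat, p = float("nan"), float("nan")
        tss_rows.append((cls, *obs, stat, p))
    pd.DataFrame(tss_rows, columns=["peak_group", "tss", "non_tss",
                                    "chisq_vs_all", "pvalue"]).to_csv(
        tssdir / "tss_frequency.tsv", sep="\t", index=False)
    stages["tss"] = {"all": all_counts}

    # known-motif enrichment of increased peaks vs random background
    motifdir = outdir / "motif_enrichment"
    motifdir.mkdir(exist_ok=True)
    sizes = {c: len(s) for c, s in genome.items()}
    inc = PeakSet([iv for iv, c in zip(peaks, diff["peak_class"]) if c == "increased"])
    if len(inc):
        width = int(np.median([iv.length for iv in inc]))
        bg = sample_random_regions(sizes, min(len(inc), 500), width,
                                   exclude=peaks, seed=cfg.seed, genome=genome)
        enr = motif_enrichment(inc, patterns, genome, bg)
        enr.to_csv(motifdir / "increased_vs_random.tsv", sep="\t", index=False)
        stages["motif_enrichment"] = {"n_target": len(inc), "n_background": len(bg)}
    else:
        log.warning("no increased peaks: motif enrichment skipped")
        stages["motif_enrichment"] = {"skipped": True}

    # expression integration
    exprdir = outdir / "expression"
    exprdir.mkdir(exist_ok=True)
    assign = assign_nearest_gene(peaks, genes, cfg.max_gene_dist_bp)
    integ = integrate_expression(diff, assign, expr.to_dict())
    integ["summary"].to_csv(exprdir / "class_log2fc_summary.tsv", sep="\t", index=False)
    stages["expression"] = {"dropped_peaks": integ["dropped_peaks"]}

    # metaplots at differential peaks
    metadir = outdir / "metaplots"
    metadir.mkdir(exist_ok=True)
    pooled = {"control": FragmentSet.concat(ctrl), "kd": FragmentSet.concat(kd)}
    for cls in ("increased", "decreased"):
        sub = PeakSet([iv for iv, c in zip(peaks, diff["peak_class"]) if c == cls])
        if not len(sub):
            continue
        profs = {}
        for cond, frags in pooled.items():
            sm, prof = metaplot(frags, sub, cfg.window_bp, cfg.bin_bp)
            profs[cond] = prof
            centers = sm.bin_centers()
        pd.DataFrame({"offset_bp": centers, **profs}).to_csv(
            metadir / f"{cls}_profile.tsv", sep="\t", index=False)

    _write_manifest(outdir, "steady_state", cfg, stages)
    return {"outdir": str(outdir), "stages": stages, "diff": diff}


def run_reprogramming(cfg: RunConfig) -> dict:
    """Factor-induction workflow: classification, metaplots, dyads, scanning."""
    cfg.require("peaks", "genome")
    cfg.require_atac("t0", "t12")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    peaks = read_bed(cfg.peaks, "BED6")
    genome = read_fasta(cfg.genome)
    t0 = FragmentSet.concat(_load_atac(cfg, "t0"))
    t12 = FragmentSet.concat(_load_atac(cfg, "t12"))
    stages["inputs"] = {"n_peaks": len(peaks), "t0_fragments": len(t0),
                        "t12_fragments": len(t12)}

    clsdir = outdir / "classification"
    clsdir.mkdir(exist_ok=True)
    result = classify_gata3_peaks(peaks, t0, t12, ClassificationConfig(scale=cfg.scale))
    labeled = PeakSet([
        GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, cls, iv.score)
        for iv, cls in zip(peaks, result["locus_class"])
    ])
    write_bed(labeled, clsdir / "classified_peaks.bed")
    result.to_csv(clsdir / "classification.tsv", sep="\t", index=False)
    class_counts = result["locus_class"].value_counts().to_dict()
    pd.Series(class_counts).rename_axis("locus_class").to_frame("n_peaks").to_csv(
        clsdir / "class_counts.tsv", sep="\t")
    stages["classification"] = {"class_counts": class_counts}

    # class-wise ATAC metaplots, t0 vs t12
    metadir = outdir / "metaplots"
    metadir.mkdir(exist_ok=True)
    for cls in sorted(class_counts):
        sub = PeakSet([iv for iv, c in zip(peaks, result["locus_class"]) if c == cls])
        sm0, p0 = metaplot(t0, sub, cfg.window_bp, cfg.bin_bp)
        _, p12 = metaplot(t12, sub, cfg.window_bp, cfg.bin_bp)
        pd.DataFrame({"offset_bp": sm0.bin_centers(), "t0": p0, "t12": p12}).to_csv(
            metadir / f"{cls}_atac_profile.tsv", sep="\t", index=False)

    # dyad profiling (control vs kd at t12, optional reference t0)
    dyaddir = outdir / "dyads"
    dyaddir.mkdir(exist_ok=True)
    mn_paths = {k: v for k, v in (cfg.mnase or {}).items()}
    have_mnase = {"control", "kd"} <= set(mn_paths)
    if have_mnase:
        mono = {}
        empty = False
        for label in ("control", "kd"):
            fs = read_bed(mn_paths[label], "BEDPE")
            fs = FragmentSet(fs.fragments, library_size=cfg.mnase_library_size)
            mono[label] = filter_mononucleosomal(fs)
            if len(mono[label]) == 0:
                empty = True
        if empty:
            log.warning("empty MNase input: dyad stages skipped")
            stages["dyads"] = {"skipped": "empty MNase input"}
            have_mnase = False
    else:
        log.warning("MNase inputs absent: dyad stages skipped")
        stages["dyads"] = {"skipped": "missing MNase input"}
    if have_mnase:
        phasing = {}
        for cls in sorted(class_counts):
            sub = PeakSet([iv for iv, c in zip(peaks, result["locus_class"]) if c == cls])
            profs = {}
            for label in ("control", "kd"):
                dp = dyad_frequency(mono[label], sub, cfg.dyad_window_bp,
                                    cfg.dyad_bin_bp)
                profs[label] = dp
                dp.matrix.to_tsv(dyaddir / f"{cls}_{label}_dyads.tsv")
            ratio = normalize_to_reference(profs["kd"], profs["control"])
            pd.DataFrame(ratio).to_csv(dyaddir / f"{cls}_kd_over_control.tsv",
                                       sep="\t", index=False)
            phasing[cls] = {
                label: asdict(phasing_score(profs[label].profile(), cfg.dyad_bin_bp))
                for label in ("control", "kd")
            }
        with open(dyaddir / "phasing_scores.json", "w") as fh:
            json.dump(phasing, fh, indent=2, sort_keys=True)
        stages["dyads"] = {"mono_fragments": {k: len(v) for k, v in mono.items()},
                           "phasing": phasing}

    # consensus-motif scanning enrichment
    scandir = outdir / "scanning"
    scandir.mkdir(exist_ok=True)
    if cfg.chip and Path(cfg.chip).exists():
        chip = read_bed(cfg.chip, "BEDPE")
        chip = FragmentSet(chip.fragments, library_size=cfg.chip_library_size)
        chip_peaks = (read_bed(cfg.chip_peaks, "BED6")
                      if cfg.chip_peaks and Path(cfg.chip_peaks).exists() else PeakSet())
        pattern = AP1_MOTIF
        if cfg.motifs and Path(cfg.motifs).exists():
            by_name = {p.name: p for p in read_motif_table(cfg.motifs)}
            pattern = by_name.get(cfg.scan_motif, pattern)
        hits = scan_genome(genome, pattern)
        sites = build_potential_sites(hits, chip_peaks)
        sizes = {c: len(s) for c, s in genome.items()}
        ctrl_regions = sample_random_regions(
            sizes, min(len(sites), 1000), 200,
            exclude=chip_peaks, seed=cfg.seed, genome=genome)
        if len(sites) > 1000:
            rng = np.random.default_rng(cfg.seed)
            keep = rng.choice(len(sites), 1000, replace=False)
            sites = PeakSet([sites[int(i)] for i in keep])
        enr = scanning_enrichment(chip, sites, ctrl_regions,
                                  window_bp=cfg.window_bp // 2, bin_bp=cfg.bin_bp)
        pd.DataFrame({"offset_bp": enr.bin_centers,
                      "motif_sites": enr.candidate_profile,
                      "random": enr.control_profile}).to_csv(
            scandir / "scanning_profiles.tsv", sep="\t", index=False)
        with open(scandir / "scanning_test.json", "w") as fh:
            json.dump({"U": enr.statistic, "pvalue": enr.pvalue,
                       "n_sites": len(sites), "n_random": len(ctrl_regions)},
                      fh, indent=2)
        stages["scanning"] = {"n_sites": len(sites), "pvalue": enr.pvalue}
    else:
        stages["scanning"] = {"skipped": "no ChIP fragments"}

    _write_manifest(outdir, "reprogramming", cfg, stages)
    return {"outdir": str(outdir), "stages": stages, "classification": result}
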
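"""Three-class accessibility classification of TF peaks, and integration of
differential accessibility with gene-expression fold changes.

A TF binding site (e.g. a GATA3 ChIP peak) is scored before (time 0) and
after (time 12 h) factor induction:

* ``newly_accessible`` — ATAC signal in the peak-center window (+/- 200 bp)
  rises more than 2-fold over time 0 AND the induced flanking region
  (+/- 1 kb) carries more than 30 normalized reads;
* ``constitutively_accessible`` — the flanking region already carries more
  than 30 normalized reads before induction;
* ``constitutively_inaccessible`` — fewer than 30 normalized reads at the
  flanks; the site stays closed.

Rules are applied in that priority order, so every peak receives exactly
one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .signal import FragmentSet, count_in_windows, normalize_counts, DEFAULT_SCALE

__all__ = [
    "LOCUS_CLASSES",
    "ClassificationConfig",
    "classify_gata3_peaks",
    "integrate_expression",
]

LOCUS_CLASSES = (
    "newly_accessible",
    "constitutively_accessible",
    "constitutively_inaccessible",
)


@dataclass
class ClassificationConfig:
    """Thresholds for the three-class peak classification.

    Defaults: +/-200 bp center window, +/-1 kb flank window, 2-fold center
    increase, 30 normalized reads (fragments per 10 million) at the flanks,
    pseudocount 1.0 (normalized units) in the fold-change ratio.
    """

    center_halfwidth_bp: int = 200
    flank_halfwidth_bp: int = 1000
    fold_increase: float = 2.0
    flank_read_cutoff: float = 30.0
    pseudocount: float = 1.0
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if min(self.center_halfwidth_bp, self.flank_halfwidth_bp,
               self.fold_increase, self.flank_read_cutoff, self.pseudocount) <= 0:
            raise ValueError("all config values must be positive")
        if self.fold_increase <= 1:
            raise ValueError("fold_increase must exceed 1")


def classify_gata3_peaks(peaks: PeakSet, atac_t0: FragmentSet, atac_t12: FragmentSet,
                         cfg: ClassificationConfig | None = None) -> pd.DataFrame:
    """Classify each TF peak as newly / constitutively accessible or
    constitutively inaccessible from pre- and post-induction ATAC fragments.

    Returns a DataFrame aligned with ``peaks`` holding the center/flank
    normalized counts, the center fold change, and ``locus_class``.

    Raises
    ------
    ValueError
        If a chromosome present in the peaks has no fragments in either
        ATAC set (naming the chromosome); genuinely empty chromosomes in
        real data should be dropped from the peak set first.
    """
    if len(peaks) == 0:
        raise ValueError("peaks must be non-empty")
    cfg = cfg or ClassificationConfig()
    for label, frags in (("t0", atac_t0), ("t12", atac_t12)):
        missing = peaks.chroms - frags.chroms
        if missing:
            raise ValueError(
                f"no {label} ATAC fragments for chromosome(s) {sorted(missing)}"
            )

    def norm_counts(frags: FragmentSet, hw: int) -> np.ndarray:
        return normalize_counts(count_in_windows(frags, peaks, hw, mode="fragment"),
                                frags.library_size, cfg.scale)

    t0_center = norm_counts(atac_t0, cfg.center_halfwidth_bp)
    t12_center = norm_counts(atac_t12, cfg.center_halfwidth_bp)
    t0_flank = norm_counts(atac_t0, cfg.flank_halfwidth_bp)
    t12_flank = norm_counts(atac_t12, cfg.flank_halfwidth_bp)

    ratio = (t12_center + cfg.pseudocount) / (t0_center + cfg.pseudocount)
    newly = (ratio > cfg.fold_increase) & (t12_flank > cfg.flank_read_cutoff)
    const_acc = ~newly & (t0_flank > cfg.flank_read_cutoff)
    classes = np.where(newly, "newly_accessible",
                       np.where(const_acc, "constitutively_accessible",
                                "constitutively_inaccessible"))
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in peaks],
            "start": [iv.start for iv in peaks],
            "end": [iv.end for iv in peaks],
            "t0_center": t0_center,
            "t12_center": t12_center,
            "t0_flank": t0_flank,
            "t12_flank": t12_flank,
            "center_fold_change": ratio,
            "locus_class": classes,
        }
    )


def integrate_expression(diff: pd.DataFrame, assignments: Sequence[str | None],
                         expr_log2fc: Mapping[str, float]) -> dict:
    """Distribute gene-expression log2 fold changes over differential-peak
    classes.

    ``diff`` is a :func:`remodelseq.signal.differential_peaks` result (its
    ``peak_class`` column is used), ``assignments`` the per-peak nearest
    gene (``None`` = unassigned), ``expr_log2fc`` a gene -> log2FC mapping.
    Genes are de-duplicated within a class. Returns a dict with per-class
    log2FC lists, a summary DataFrame (n, median, quartiles) and the number
    of peaks dropped for missing assignment/expression.
    """
    if len(assignments) != len(diff):
        raise ValueError("assignments length differs from diff result")
    per_class: dict[str, dict[str, float]] = {
        "increased": {}, "decreased": {}, "unchanged": {}
    }
    dropped = 0
    for cls, gene in zip(diff["peak_class"], assignments):
        if gene is None or gene not in expr_log2fc:
            dropped += 1
            continue
        per_class[cls].setdefault(gene, float(expr_log2fc[gene]))
    values = {cls: sorted(d.values()) for cls, d in per_class.items()}
    if all(len(v) == 0 for v in values.values()):
        raise ValueError("no peak class retained any expressed gene")
    rows = []
    for cls, v in values.items():
        arr = np.array(v, dtype=float)
        rows.append(
            (cls, len(arr),
             float(np.median(arr)) if len(arr) else float("nan"),
             float(np.percentile(arr, 25)) if len(arr) else float("nan"),
             float(np.percentile(arr, 75)) if len(arr) else float("nan"))
        )
    summary = pd.DataFrame(rows, columns=["peak_class", "n_genes", "median_log2fc",
                                          "q25", "q75"])
    return {"log2fc": values, "summary": summary, "dropped_peaks": dropped}
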
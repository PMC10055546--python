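"""Fragment-to-signal conversion: windowed counts, library-size
normalization, metaplot/heatmap matrices, and differential peak statistics.

Counts are normalized to fragments per 10 million library fragments
(``scale=1e7``), the unit in which accessibility-classification thresholds
such as "30 normalized reads" are expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import PeakSet

__all__ = [
    "FragmentSet",
    "SignalMatrix",
    "count_in_windows",
    "normalize_counts",
    "metaplot",
    "differential_peaks",
    "category_chisq",
    "write_bedgraph",
]

DEFAULT_SCALE = 1e7


class FragmentSet:
    """Paired-end-derived fragments (chrom, start, end) with library metadata.

    ``library_size`` is the total number of mapped fragments in the
    originating library; it may exceed the number of fragments held here
    (e.g. when only a genomic slice is retained) but never be smaller.
    """

    def __init__(self, fragments: pd.DataFrame, library_size: int | None = None,
                 condition: str | None = None, replicate: str | None = None) -> None:
        df = fragments[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"fragment with start >= end: {bad.chrom}:{bad.start}-{bad.end}")
        self.fragments = df.reset_index(drop=True)
        if library_size is None:
            library_size = len(df)
        if library_size < len(df):
            raise ValueError("library_size smaller than number of fragments")
        self.library_size = int(library_size)
        self.condition = condition
        self.replicate = replicate
        self._index: dict[str, dict[str, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.fragments)

    def __repr__(self) -> str:
        return (f"FragmentSet({len(self)} fragments, library_size={self.library_size}, "
                f"condition={self.condition!r}, replicate={self.replicate!r})")

    @property
    def chroms(self) -> set[str]:
        return set(self.fragments["chrom"].unique())

    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    def midpoints(self) -> np.ndarray:
        """Fragment midpoints; even-length fragments use start + length // 2."""
        f = self.fragments
        return (f["start"] + (f["end"] - f["start"]) // 2).to_numpy()

    def filter_lengths(self, min_bp: int, max_bp: int) -> "FragmentSet":
        ln = self.lengths()
        keep = (ln >= min_bp) & (ln <= max_bp)
        return FragmentSet(self.fragments[keep], library_size=self.library_size,
                           condition=self.condition, replicate=self.replicate)

    @classmethod
    def concat(cls, parts: Sequence["FragmentSet"], condition: str | None = None) -> "FragmentSet":
        """Pool replicates; library sizes add."""
        if not parts:
            raise ValueError("nothing to concatenate")
        df = pd.concat([p.fragments for p in parts], ignore_index=True)
        lib = sum(p.library_size for p in parts)
        return cls(df, library_size=lib, condition=condition or parts[0].condition)

    def write_bedpe(self, path) -> None:
        """Emit fragments as degenerate BEDPE (both ends spanning the fragment)."""
        with open(path, "w") as fh:
            for row in self.fragments.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.chrom}\t{row.start}\t{row.end}\n")

    # -- per-chromosome sorted views ------------------------------------
    def _chrom_index(self, chrom: str) -> dict[str, np.ndarray] | None:
        if chrom not in self._index:
            sub = self.fragments[self.fragments["chrom"] == chrom]
            if len(sub) == 0:
                self._index[chrom] = None  # type: ignore[assignment]
            else:
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                order = np.argsort(starts, kind="stable")
                s = starts[order]
                e = ends[order]
                mids = s + (e - s) // 2
                self._index[chrom] = {
                    "starts": s,
                    "ends_by_start": e,
                    "mids_by_start": mids,
                    "ends_sorted": np.sort(ends),
                    "mids_sorted": np.sort(mids),
                    "max_len": int((e - s).max()),
                }
        return self._index[chrom]


def _window_bounds(anchors: PeakSet, half_width_bp: int) -> pd.DataFrame:
    centers = anchors.centers()
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in anchors],
            "wstart": centers - half_width_bp,
            "wend": centers + half_width_bp,
        }
    )


def count_in_windows(frags: FragmentSet, anchors: PeakSet, half_width_bp: int,
                     mode: str = "fragment") -> np.ndarray:
    """Raw fragment counts in anchor-centered windows ``[c-hw, c+hw)``.

    ``mode="fragment"`` counts fragments with any overlap of the window;
    ``mode="midpoint"`` counts fragments whose midpoint lies in the window
    (half-open on the right).
    """
    if half_width_bp <= 0:
        raise ValueError("half_width_bp must be > 0")
    if mode not in {"fragment", "midpoint"}:
        raise ValueError(f"unknown mode {mode!r}")
    win = _window_bounds(anchors, half_width_bp)
    counts = np.zeros(len(anchors), dtype=np.int64)
    for chrom, grp in win.groupby("chrom", sort=False):
        idx = frags._chrom_index(chrom)
        if idx is None:
            continue
        ws = grp["wstart"].to_numpy()
        we = grp["wend"].to_numpy()
        if mode == "midpoint":
            mids = idx["mids_sorted"]
            c = np.searchsorted(mids, we, side="left") - np.searchsorted(mids, ws, side="left")
        else:
            # overlap iff start < wend and end > wstart; since start < end,
            # #(start<wend & end<=wstart) == #(end<=wstart)
            c = (np.searchsorted(idx["starts"], we, side="left")
                 - np.searchsorted(idx["ends_sorted"], ws, side="right"))
        counts[grp.index] = c
    return counts


def normalize_counts(raw, library_size: int, scale: float = DEFAULT_SCALE):
    """Library-size normalization: ``raw * scale / library_size``.

    With the default scale this is fragments per 10 million library
    fragments, the unit of the ">30 normalized reads" threshold.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(raw, dtype=float) * (scale / library_size)


@dataclass
class SignalMatrix:
    """Anchors x position-bins matrix of (normalized) counts.

    Bin ``j`` covers offsets ``[-window_bp + j*bin_bp, -window_bp + (j+1)*bin_bp)``
    relative to anchor centers.
    """

    values: np.ndarray
    anchors: PeakSet
    window_bp: int
    bin_bp: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        nbins = (2 * self.window_bp) // self.bin_bp
        if self.values.shape != (len(self.anchors), nbins):
            raise ValueError(
                f"values shape {self.values.shape} != ({len(self.anchors)}, {nbins})"
            )
        if (self.values < 0).any():
            raise ValueError("negative values in SignalMatrix")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_centers(self) -> np.ndarray:
        """Offsets of bin centers relative to anchor centers (bp)."""
        edges = np.arange(self.n_bins + 1) * self.bin_bp - self.window_bp
        return (edges[:-1] + edges[1:]) / 2.0

    def profile(self) -> np.ndarray:
        """Per-bin mean across anchors (the metaplot trace)."""
        return self.values.mean(axis=0)

    def ordered_by_total(self) -> np.ndarray:
        """Row order for heatmaps: descending row sum."""
        return np.argsort(-self.values.sum(axis=1), kind="stable")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{int(c):+d}" for c in self.bin_centers()])
        df.insert(0, "anchor", [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.anchors])
        df.to_csv(path, sep="\t", index=False)


def metaplot(frags: FragmentSet, anchors: PeakSet, window_bp: int, bin_bp: int,
             mode: str = "fragment", normalize: bool = True,
             scale: float = DEFAULT_SCALE) -> tuple[SignalMatrix, np.ndarray]:
    """Anchor-centered signal matrix plus its column-mean profile.

    Each in-window fragment contributes exactly one event, placed at its
    midpoint (clipped into the window for ``mode="fragment"``, where any
    overlapping fragment counts; dropped if outside for ``mode="midpoint"``).
    The matrix total therefore equals the :func:`count_in_windows` total
    for the same mode.
    """
    if len(anchors) == 0:
        raise ValueError("anchors must be non-empty")
    if (2 * window_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*window_bp")
    if mode not in {"fragment", "midpoint"}:
        raise ValueError(f"unknown mode {mode!r}")
    nbins = (2 * window_bp) // bin_bp
    values = np.zeros((len(anchors), nbins), dtype=float)
    win = _window_bounds(anchors, window_bp)
    for chrom, grp in win.groupby("chrom", sort=False):
        idx = frags._chrom_index(chrom)
        if idx is None:
            continue
        starts = idx["starts"]
        ends = idx["ends_by_start"]
        mids = idx["mids_by_start"]
        maxlen = idx["max_len"]
        for ai, ws, we in zip(grp.index, grp["wstart"], grp["wend"]):
            if mode == "midpoint":
                lo = np.searchsorted(idx["mids_sorted"], ws, side="left")
                hi = np.searchsorted(idx["mids_sorted"], we, side="left")
                ev = idx["mids_sorted"][lo:hi]
            else:
                lo = np.searchsorted(starts, ws - maxlen, side="left")
                hi = np.searchsorted(starts, we, side="left")
                sel = ends[lo:hi] > ws
                ev = np.clip(mids[lo:hi][sel], ws, we - 1)
            if len(ev):
                np.add.at(values[ai], (ev - ws) // bin_bp, 1.0)
    norm_label = "raw"
    if normalize:
        values = normalize_counts(values, frags.library_size, scale)
        norm_label = f"per_{scale:g}_fragments"
    sm = SignalMatrix(values, anchors, window_bp, bin_bp, normalization=norm_label)
    return sm, sm.profile()


def differential_peaks(counts_a, counts_b, lib_sizes_a, lib_sizes_b,
                       fc_cutoff: float = 2.0, fdr_cutoff: float = 0.01,
                       scale: float = DEFAULT_SCALE,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Differential peak calls between condition A and condition B.

    Per peak, replicate counts are pooled within condition and tested with a
    two-sided Fisher exact test on the 2x2 table of (in-peak, rest-of-library)
    fragments, followed by Benjamini-Hochberg FDR across peaks. A peak is
    classed ``increased`` (in B relative to A) iff FDR < ``fdr_cutoff``, the
    fold change of pooled normalized counts exceeds ``fc_cutoff``, and every
    replicate agrees in direction (each B replicate above A's pooled
    normalized mean and each A replicate below B's); ``decreased`` is
    symmetric; everything else, including all-zero peaks (p = 1), is
    ``unchanged``.

    Returns a DataFrame with columns ``count_a``, ``count_b`` (pooled,
    normalized), ``log2fc``, ``pvalue``, ``fdr``, ``direction_consistent``,
    ``peak_class``.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=np.int64))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=np.int64))
    if counts_a.shape[0] == 1 and counts_a.shape[1] != counts_b.shape[1]:
        pass  # single-replicate row vectors are fine
    lib_a = np.asarray(lib_sizes_a, dtype=np.int64).ravel()
    lib_b = np.asarray(lib_sizes_b, dtype=np.int64).ravel()
    # orient as (n_peaks, n_reps)
    if counts_a.shape[1] != len(lib_a) and counts_a.shape[0] == len(lib_a):
        counts_a = counts_a.T
    if counts_b.shape[1] != len(lib_b) and counts_b.shape[0] == len(lib_b):
        counts_b = counts_b.T
    if counts_a.shape[1] != len(lib_a) or counts_b.shape[1] != len(lib_b):
        raise ValueError("replicate count / library size mismatch")
    if counts_a.shape[0] != counts_b.shape[0]:
        raise ValueError("conditions cover different numbers of peaks")
    if (lib_a <= 0).any() or (lib_b <= 0).any():
        raise ValueError("all library sizes must be > 0")

    n = counts_a.shape[0]
    pooled_a = counts_a.sum(axis=1)
    pooled_b = counts_b.sum(axis=1)
    tot_a = int(lib_a.sum())
    tot_b = int(lib_b.sum())
    norm_a = pooled_a * (scale / tot_a)
    norm_b = pooled_b * (scale / tot_b)
    log2fc = np.log2((norm_b + pseudocount) / (norm_a + pseudocount))

    pvals = np.ones(n)
    for i in range(n):
        a, b = int(pooled_a[i]), int(pooled_b[i])
        if a == 0 and b == 0:
            continue
        _, pvals[i] = stats.fisher_exact(
            [[a, tot_a - a], [b, tot_b - b]], alternative="two-sided"
        )
    fdr = multipletests(pvals, method="fdr_bh")[1]

    rep_norm_a = counts_a * (scale / lib_a)
    rep_norm_b = counts_b * (scale / lib_b)
    mean_a = rep_norm_a.mean(axis=1)
    mean_b = rep_norm_b.mean(axis=1)
    up_consistent = (rep_norm_b > mean_a[:, None]).all(axis=1) & \
                    (rep_norm_a < mean_b[:, None]).all(axis=1)
    down_consistent = (rep_norm_b < mean_a[:, None]).all(axis=1) & \
                      (rep_norm_a > mean_b[:, None]).all(axis=1)

    log2_cut = np.log2(fc_cutoff)
    sig = fdr < fdr_cutoff
    classes = np.full(n, "unchanged", dtype=object)
    classes[sig & (log2fc > log2_cut) & up_consistent] = "increased"
    classes[sig & (log2fc < -log2_cut) & down_consistent] = "decreased"
    direction = np.where(up_consistent, 1, np.where(down_consistent, -1, 0))

    return pd.DataFrame(
        {
            "count_a": norm_a,
            "count_b": norm_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction_consistent": direction,
            "peak_class": classes,
        }
    )


def category_chisq(observed, expected_from) -> tuple[float, float]:
    """Pearson chi-square of observed category counts against the
    proportions of a reference count vector.

    Returns ``(statistic, p_value)``.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(expected_from, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("observed and reference have different categories")
    if (ref <= 0).any():
        raise ValueError("zero (or negative) expected cell")
    expected = ref / ref.sum() * obs.sum()
    stat, p = stats.chisquare(obs, expected)
    return float(stat), float(p)


def write_bedgraph(frags: FragmentSet, path, bin_bp: int = 10,
                   scale: float = DEFAULT_SCALE,
                   chrom_sizes: dict[str, int] | None = None) -> None:
    """Binned normalized fragment-overlap coverage as bedGraph (zero bins
    omitted)."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    factor = scale / frags.library_size
    with open(path, "w") as fh:
        for chrom in sorted(frags.chroms):
            sub = frags.fragments[frags.fragments["chrom"] == chrom]
            size = (chrom_sizes or {}).get(chrom, int(sub["end"].max()))
            nbins = -(-size // bin_bp)
            delta = np.zeros(nbins + 1)
            sb = np.minimum(sub["start"].to_numpy() // bin_bp, nbins - 1)
            eb = np.minimum((sub["end"].to_numpy() - 1) // bin_bp, nbins - 1)
            np.add.at(delta, sb, 1.0)
            np.add.at(delta, eb + 1, -1.0)
            cov = np.cumsum(delta)[:nbins] * factor
            for j in np.nonzero(cov)[0]:
                fh.write(f"{chrom}\t{j * bin_bp}\t{min((j + 1) * bin_bp, size)}\t{cov[j]:g}\n")
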
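"""Nucleosome dyad profiling from MNase fragments.

Mono-nucleosomal fragments (120-170 bp, closed bounds) protect roughly one
nucleosome of DNA; their midpoints approximate nucleosome dyads. Binned
midpoint (dyad) frequencies around anchor loci, normalized to a reference
timepoint, reveal nucleosome repositioning; a phasing score quantifies the
regular (~190 bp spaced) arrays that flank bound TF sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import PeakSet
from .signal import FragmentSet, SignalMatrix, metaplot

__all__ = [
    "DyadProfile",
    "PhasingScore",
    "filter_mononucleosomal",
    "dyad_frequency",
    "normalize_to_reference",
    "phasing_score",
]

MONO_NUC_BOUNDS = (120, 170)


@dataclass
class DyadProfile:
    """Anchors x bins matrix of mono-nucleosomal fragment midpoint counts.

    ``library_size`` (total mapped fragments of the source library) is kept
    so reference normalization can correct for sequencing depth.
    """

    matrix: SignalMatrix
    fragment_length_bounds: tuple[int, int] = MONO_NUC_BOUNDS
    reference_label: str = ""
    library_size: int | None = None

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values

    def profile(self) -> np.ndarray:
        return self.matrix.profile()

    def bin_centers(self) -> np.ndarray:
        return self.matrix.bin_centers()


@dataclass
class PhasingScore:
    """Flanking-array contrast and dominant nucleosome spacing."""

    amplitude: float
    period_bp: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def filter_mononucleosomal(frags: FragmentSet, min_bp: int = 120,
                           max_bp: int = 170) -> FragmentSet:
    """Retain fragments with min_bp <= length <= max_bp (closed bounds).

    Duplicate fragments are retained; capture MNase protocols keep
    duplicates because deep local coverage makes them expected.
    """
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    return frags.filter_lengths(min_bp, max_bp)


def dyad_frequency(frags: FragmentSet, anchors: PeakSet, window_bp: int,
                   bin_bp: int = 10, normalize: bool = False,
                   reference_label: str = "") -> DyadProfile:
    """Per-anchor histogram of fragment midpoints (dyads) in centered bins.

    ``frags`` should already be restricted to mono-nucleosomal lengths.
    The matrix total equals the number of in-window midpoints.
    """
    if bin_bp > window_bp:
        raise ValueError("bin_bp must be <= window_bp")
    sm, _ = metaplot(frags, anchors, window_bp, bin_bp, mode="midpoint",
                     normalize=normalize)
    return DyadProfile(sm, reference_label=reference_label,
                       library_size=frags.library_size)


def normalize_to_reference(profile: DyadProfile, reference: DyadProfile,
                           pseudocount: float = 0.5) -> np.ndarray:
    """Elementwise dyad-frequency ratio against a reference timepoint.

    Both matrices are first depth-scaled to a common library size so the
    ratio reflects nucleosome redistribution, not sequencing depth; a value
    of 1 means no change. Returns the anchors x bins ratio matrix.
    """
    p = profile.values
    r = reference.values
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {r.shape}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if profile.library_size is None or reference.library_size is None:
        raise ValueError("both profiles need a library_size for depth scaling")
    target = (profile.library_size + reference.library_size) / 2.0
    return ((p * (target / profile.library_size) + pseudocount)
            / (r * (target / reference.library_size) + pseudocount))


def phasing_score(mean_profile: np.ndarray, bin_bp: int,
                  expected_period_bp: int = 190,
                  period_search_bp: tuple[int, int] = (120, 260)) -> PhasingScore:
    """Score a mean dyad profile for a phased nucleosome array.

    ``amplitude`` is the mean signal at the +/-1 and +/-2 expected
    nucleosome positions minus the central (NDR) signal, clipped at zero;
    ``period_bp`` is the autocorrelation-dominant spacing searched over
    nucleosome-plausible lags.
    """
    prof = np.asarray(mean_profile, dtype=float)
    nbins = len(prof)
    step = expected_period_bp // bin_bp
    if nbins < 2 * step:
        raise ValueError("profile too short for the expected period")
    center = nbins // 2
    picks = [center + k * step for k in (-2, -1, 1, 2)
             if 0 <= center + k * step < nbins]
    amplitude = max(0.0, float(np.mean(prof[picks]) - prof[center]))

    x = prof - prof.mean()
    lo = max(1, period_search_bp[0] // bin_bp)
    hi = min(nbins - 1, period_search_bp[1] // bin_bp)
    if hi < lo or np.allclose(x, 0):
        return PhasingScore(amplitude, float(expected_period_bp))
    ac = np.array([np.dot(x[:-lag], x[lag:]) for lag in range(lo, hi + 1)])
    period = (lo + int(np.argmax(ac))) * bin_bp
    return PhasingScore(amplitude, float(period))
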
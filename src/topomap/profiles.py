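"""Coverage-track processing: smoothing, normalization, ratios, masking.

The analyses operate on per-base read-coverage tracks, one per strand per
sample (immunoprecipitate, input, mock IP).  The canonical pipeline is

    rpm_normalize -> smooth_circular(200 bp) -> combine_strands ->
    ratio_track -> mask_from_mock -> [gc_normalize, dosage_normalize]

which mirrors how IP/input enrichment maps are conventionally built for a
circular bacterial chromosome: read counts are scaled to reads-per-million,
smoothed with a 200 bp centered moving average, forward and reverse signals
are added, and the IP track is divided by the input track position by
position.  Regions that light up in a mock immunoprecipitation (rRNA operons,
tRNA clusters, IS elements) carry no protein-specific information and are
masked before any peak calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .genome import GenomeSpec

__all__ = [
    "StrandedProfile",
    "RatioTrack",
    "NormalizationParams",
    "smooth_circular",
    "rpm_normalize",
    "combine_strands",
    "ratio_track",
    "mask_from_mock",
    "gc_normalize",
    "dosage_normalize",
    "sliding_mean",
    "track_pearson",
    "gc_content_track",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Tunable constants of the normalization pipeline.

    ``pseudocount`` is expressed in reads per smoothing window; the
    per-position pseudocount added to both the IP and input tracks is
    ``pseudocount / smooth_window``.
    """

    smooth_window: int = 200
    pseudocount: float = 1.0
    rpm_scale: float = 1e6
    mask_fold_threshold: float = 2.0

    def __post_init__(self):
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class StrandedProfile:
    """Per-base forward and reverse read signal for one sample.

    ``library_size`` defaults to the total signal at construction and is kept
    through smoothing/normalization so that reads-per-million scaling is
    always relative to the original sequencing depth.
    """

    fwd: np.ndarray
    rev: np.ndarray
    genome: GenomeSpec
    library_size: float | None = None

    def __post_init__(self):
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        if self.fwd.shape != self.rev.shape or self.fwd.ndim != 1:
            raise ValueError("fwd and rev must be 1-D arrays of equal length")
        if len(self.fwd) != self.genome.length:
            raise ValueError(
                f"profile length {len(self.fwd)} != genome length {self.genome.length}"
            )
        if np.any(self.fwd < 0) or np.any(self.rev < 0):
            raise ValueError("read counts must be non-negative")
        if self.library_size is None:
            self.library_size = float(self.fwd.sum() + self.rev.sum())

    def __len__(self) -> int:
        return len(self.fwd)

    def total(self) -> np.ndarray:
        return self.fwd + self.rev


@dataclass
class RatioTrack:
    """A normalized per-position (or per-bin) signal with an optional mask.

    ``mask`` is a boolean array, True where the position is excluded from
    downstream statistics.
    """

    values: np.ndarray
    bin_size: int = 1
    mask: np.ndarray | None = None
    genome: GenomeSpec | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must have equal shape")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def mask_intervals(self) -> list[tuple[int, int]]:
        """Masked runs as [start, end) intervals in bp (BED-compatible)."""
        m = self.mask
        if not m.any():
            return []
        edges = np.flatnonzero(np.diff(m.astype(int)))
        boundaries = np.concatenate([[0], edges + 1, [len(m)]])
        out = []
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if m[a]:
                out.append((int(a * self.bin_size), int(b * self.bin_size)))
        return out

    def plot(self, ax=None, **kwargs):
        """Quick look at the track (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        x = np.arange(len(self.values)) * self.bin_size
        y = np.where(self.mask, np.nan, self.values)
        ax.plot(x, y, lw=0.7, **kwargs)
        ax.set_xlabel("genome position (bp)")
        ax.set_ylabel("ratio")
        return ax


def smooth_circular(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with circular wrap.

    Even windows are centered asymmetrically with ``floor(window/2)``
    positions taken on the left.  The track total is conserved.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(values):
        raise ValueError(f"window {window} larger than track length {len(values)}")
    if window == 1:
        return values.copy()
    return ndimage.uniform_filter1d(values, size=window, mode="wrap")


def rpm_normalize(profile: StrandedProfile) -> StrandedProfile:
    """Scale both strands to reads-per-million of the library."""
    if not profile.library_size or profile.library_size <= 0:
        raise ValueError("cannot RPM-normalize an empty profile")
    f = 1e6 / profile.library_size
    return StrandedProfile(
        fwd=profile.fwd * f,
        rev=profile.rev * f,
        genome=profile.genome,
        library_size=1e6,
    )


def combine_strands(profile: StrandedProfile) -> np.ndarray:
    """Elementwise forward + reverse signal."""
    return profile.fwd + profile.rev


def ratio_track(
    ip: np.ndarray,
    input_: np.ndarray,
    pseudocount: float = 1.0 / 200,
    center: str = "median",
    genome: GenomeSpec | None = None,
) -> RatioTrack:
    """Per-position (ip + p) / (input + p).

    With ``center="median"`` (default) the track is rescaled so its
    genome-wide median is 1, which is robust to the few strong peaks;
    ``center="none"`` returns the raw ratio.
    """
    ip = np.asarray(ip, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if ip.shape != input_.shape:
        raise ValueError("ip and input tracks must have equal length")
    if pseudocount <= 0 and not np.all(input_ > 0):
        raise ValueError("zero-coverage input requires a positive pseudocount")
    vals = (ip + pseudocount) / (input_ + pseudocount)
    if center == "median":
        med = np.median(vals)
        if med > 0:
            vals = vals / med
    elif center != "none":
        raise ValueError("center must be 'median' or 'none'")
    return RatioTrack(values=vals, bin_size=1, genome=genome)


def mask_from_mock(
    ratio: RatioTrack,
    mock_ratio: RatioTrack,
    fold_threshold: float = 2.0,
    smooth_window: int = 200,
) -> RatioTrack:
    """Mask positions where the mock-IP enrichment exceeds ``fold_threshold``.

    The mock ratio is smoothed over ``smooth_window`` first; positions whose
    smoothed mock signal is below the threshold are never masked.
    """
    if len(ratio) != len(mock_ratio) or ratio.bin_size != mock_ratio.bin_size:
        raise ValueError("ratio and mock ratio must share binning")
    mock = smooth_circular(mock_ratio.values, min(smooth_window, len(mock_ratio)))
    new_mask = ratio.mask | (mock >= fold_threshold)
    return replace(ratio, mask=new_mask)


def gc_content_track(genome: GenomeSpec, window: int) -> np.ndarray:
    """Per-bin GC fraction over circular non-overlapping ``window`` bp bins."""
    if genome.sequence is None:
        raise ValueError("genome sequence required for GC computation")
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1")
    is_gc = np.isin(seq, [b"G", b"C"]).astype(float)
    n_bins = int(np.ceil(genome.length / window))
    pad = n_bins * window - genome.length
    if pad:
        is_gc = np.concatenate([is_gc, is_gc[:pad]])  # wrap the last bin
    return is_gc.reshape(n_bins, window).mean(axis=1)


def gc_normalize(ratio: RatioTrack, genome: GenomeSpec, window: int = 60_000) -> RatioTrack:
    """Remove the linear dependence of the ratio on windowed GC content.

    The per-bin mean ratio is regressed on the per-bin GC fraction by least
    squares; every position is divided by the fitted value of its bin, and
    the track is rescaled to preserve the genome-wide mean.
    """
    gc = gc_content_track(genome, window)
    n_bins = len(gc)
    bin_idx = np.minimum(np.arange(len(ratio)) // window, n_bins - 1)
    valid = ~ratio.mask
    bin_mean = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = valid & (bin_idx == b)
        if sel.any():
            bin_mean[b] = ratio.values[sel].mean()
    ok = ~np.isnan(bin_mean)
    if gc[ok].std() < 1e-9:
        warnings.warn("constant GC content; gc_normalize is the identity")
        return replace(ratio, values=ratio.values.copy())
    slope, intercept = np.polyfit(gc[ok], bin_mean[ok], 1)
    fitted = intercept + slope * gc
    fitted = np.clip(fitted, 1e-9, None)
    vals = ratio.values / fitted[bin_idx]
    before = ratio.values[valid].mean()
    after = vals[valid].mean()
    if after > 0:
        vals = vals * (before / after)
    return replace(ratio, values=vals)


def dosage_normalize(ratio: RatioTrack, dosage: np.ndarray) -> RatioTrack:
    """Divide the track by a per-position copy-number (dosage) track."""
    dosage = np.asarray(dosage, dtype=float)
    if dosage.shape != ratio.values.shape:
        raise ValueError("dosage track must match the ratio binning")
    if np.any(dosage <= 0):
        raise ValueError("dosage must be strictly positive")
    return replace(ratio, values=ratio.values / dosage)


def sliding_mean(values: np.ndarray, window: int, step: int | None = None):
    """Circular sliding mean reported at window centers.

    Returns ``(centers, means)``.  ``step`` defaults to ``window``
    (non-overlapping bins).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window > n:
        raise ValueError("window larger than track")
    if step is None:
        step = window
    starts = np.arange(0, n, step)
    ext = np.concatenate([values, values[:window]])
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    means = (cs[starts + window] - cs[starts]) / window
    centers = (starts + window // 2) % n
    return centers, means


def track_pearson(a: np.ndarray, b: np.ndarray, bin: int = 1000) -> float:
    """Pearson correlation of two tracks after averaging into ``bin`` bp bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must have equal length")
    n_bins = len(a) // bin
    if n_bins < 2:
        raise ValueError("need at least two bins")
    ab = a[: n_bins * bin].reshape(n_bins, bin).mean(axis=1)
    bb = b[: n_bins * bin].reshape(n_bins, bin).mean(axis=1)
    if ab.std() == 0 or bb.std() == 0:
        raise ValueError("correlation undefined for a constant track")
    r, _ = stats.pearsonr(ab, bb)
    return float(r)
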
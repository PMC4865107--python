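"""Replication analysis: marker frequency, fork positions, comet null model.

Marker-frequency analysis reads replication state off sequencing coverage:
in a synchronized population the ratio of a replicating sample's coverage to
a non-replicating reference is ~2 over already-replicated loci and ~1 over
unreplicated ones, and the positions where the slope of this profile changes
mark the replication forks.

The "comet" null model asks what protein occupancy would look like if the
protein simply tracked the replication forks: each fork trails a comet of
fixed genomic length (optionally the mark persists for a fixed time after
replication), forks move at constant speed v = L/C down each replichore, and
the population is in steady exponential growth so cell ages follow the
distribution f(a) = (2 ln 2 / T) 2^(-a/T) on [0, T).  Under this model the
expected occupancy O(s) is exactly proportional to the gene dosage D(s) at
every locus, for any comet length, persistence time or degree of round
overlap -- so occupancy that does NOT follow dosage (e.g. a terminus gap)
rejects the model.

Closed forms used (locus at distance l down its replichore, tau the total
occupancy window per replication event, capped at one generation):

    D(l) = 2 ** ((C + D - l/v) / T)            (Cooper-Helmstetter dosage)
    O(l) = 2 * (1 - 2 ** (-tau/T)) * D(l)      (expected occupied copies)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec
from .profiles import StrandedProfile, rpm_normalize

__all__ = [
    "MarkerFrequencyTrack",
    "CometModelParams",
    "BreakpointFit",
    "marker_frequency",
    "detect_slope_breaks",
    "fork_distances",
    "simulate_comet_occupancy",
    "monte_carlo_comet",
    "flatness_stat",
    "MarkerFrequencyModel",
    "MarkerFrequencyResults",
    "CometModel",
]


@dataclass
class MarkerFrequencyTrack:
    """Binned replicating/non-replicating coverage ratio, baseline 1."""

    values: np.ndarray          # NaN where the reference bin was empty
    bin_size: int = 10_000
    fully_replicated: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class CometModelParams:
    """Parameters of the replication-coupled occupancy null model.

    Times in minutes, lengths in bp.  ``v`` defaults to L/C (forks finish a
    replichore in exactly one C period).  ``persistence`` extends the
    occupancy window after the comet has passed; 0 gives the pure comet.
    """

    L: int = 2_320_000
    C: float = 40.0
    D: float = 20.0
    T: float = 60.0
    v: float | None = None
    comet_len: int = 200_000
    persistence: float = 0.0
    overlapping_rounds: bool = False

    def __post_init__(self):
        if min(self.C, self.T) <= 0 or self.D < 0 or self.persistence < 0:
            raise ValueError("periods must be positive (D, persistence >= 0)")
        v = self.fork_speed
        if v * self.C < self.L - 1e-6:
            raise ValueError("v * C must cover the replichore (incomplete replication)")
        if self.overlapping_rounds and self.C + self.D <= self.T:
            raise ValueError("overlapping rounds require C + D > T")
        if not self.overlapping_rounds and self.C + self.D > self.T:
            raise ValueError("C + D > T implies overlapping rounds")

    @property
    def fork_speed(self) -> float:
        return self.v if self.v is not None else self.L / self.C


@dataclass
class BreakpointFit:
    breakpoints: list[int]        # genome coordinates, bp
    segment_slopes: list[float]   # per segment between consecutive knots
    rss: float
    knots: list[int] | None = None
    fitted: np.ndarray | None = None


def marker_frequency(
    sample: StrandedProfile,
    reference: StrandedProfile,
    bin_size: int = 10_000,
) -> MarkerFrequencyTrack:
    """Binned sample/reference coverage ratio, lowest-decile bins scaled to 1.

    Both profiles are RPM-normalized internally; bins with an empty reference
    are masked (NaN).  When the rescaled track is essentially flat the track
    is flagged ``fully_replicated`` (a flat profile is what both a G1 and a
    G2 population produce; the flag records that no fork structure is
    visible).
    """
    if len(sample) != len(reference):
        raise ValueError("profiles must share the genome")
    s = rpm_normalize(sample).total()
    r = rpm_normalize(reference).total()
    n_bins = len(s) // bin_size
    if n_bins < 2:
        raise ValueError("genome too short for this bin size")
    sb = s[: n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1)
    rb = r[: n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1)
    vals = np.full(n_bins, np.nan)
    ok = rb > 0
    vals[ok] = sb[ok] / rb[ok]
    finite = vals[np.isfinite(vals)]
    decile = np.quantile(finite, 0.1)
    baseline = finite[finite <= decile].mean()
    if baseline > 0:
        vals = vals / baseline
    flat = np.nanmax(vals) - np.nanmin(vals) < 0.1
    return MarkerFrequencyTrack(values=vals, bin_size=bin_size, fully_replicated=bool(flat))


def _fit_arc_two_knots(x: np.ndarray, y: np.ndarray, k1: float, k2: float):
    """Continuous 3-segment piecewise-linear least squares with fixed knots."""
    A = np.column_stack([
        np.ones_like(x), x,
        np.maximum(x - k1, 0.0), np.maximum(x - k2, 0.0),
    ])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((y - A @ coef) ** 2).sum())
    return rss, coef


def _arc_foot(x: np.ndarray, y: np.ndarray, baseline: float):
    """Best two-knot fit on one replichore arc; returns the fork 'foot'.

    The foot is the knot at which the profile reaches the unreplicated
    baseline: among knots with a non-negligible slope change, the one whose
    fitted value is closest to the baseline.  Coarse-to-fine grid search at
    bin resolution.
    """
    n = len(x)
    step = max(1, n // 60)
    interior = np.arange(1, n - 1)

    def search(c1, c2):
        best = (np.inf, None, None)
        for k1 in c1:
            for k2 in c2:
                if k2 <= k1:
                    continue
                rss, coef = _fit_arc_two_knots(x, y, float(k1), float(k2))
                if rss < best[0]:
                    best = (rss, (k1, k2), coef)
        return best

    cand = interior[::step]
    rss, (k1, k2), coef = search(cand, cand)
    fine1 = [k for k in range(max(1, k1 - step), min(n - 1, k1 + step + 1))]
    fine2 = [k for k in range(max(1, k2 - step), min(n - 1, k2 + step + 1))]
    rss, (k1, k2), coef = search(fine1, fine2)
    slopes = [coef[1], coef[1] + coef[2], coef[1] + coef[2] + coef[3]]
    dslope = {k1: coef[2], k2: coef[3]}
    scale = max(abs(s) for s in slopes) or 1.0
    significant = [k for k in (k1, k2) if abs(dslope[k]) > 0.1 * scale]
    if not significant:
        significant = [k1 if abs(coef[2]) >= abs(coef[3]) else k2]

    def fitted_at(k):
        return coef[0] + coef[1] * k + coef[2] * max(k - k1, 0) + coef[3] * max(k - k2, 0)

    foot = min(significant, key=lambda k: abs(fitted_at(k) - baseline))
    fitted = (coef[0] + coef[1] * x + coef[2] * np.maximum(x - k1, 0)
              + coef[3] * np.maximum(x - k2, 0))
    return int(foot), slopes, rss, fitted


def detect_slope_breaks(
    mf: MarkerFrequencyTrack,
    n_breaks: int = 2,
    anchor: int | None = None,
) -> BreakpointFit:
    """Locate the two fork breakpoints by segmented linear least squares.

    The circular track is cut at the origin (``anchor`` bin, default the
    profile maximum) and at the terminus (profile minimum) into its two
    replichore arcs.  Each arc is fitted with a continuous 3-segment
    piecewise-linear function whose two knots are grid-searched at bin
    resolution, and the knot at which the profile reaches the unreplicated
    baseline -- the fork foot -- is reported as that replichore's
    breakpoint.  A flat profile returns no breakpoints.
    """
    y = mf.values
    n = len(y)
    if n < 3 * (n_breaks + 1):
        raise ValueError("too few bins for the requested number of breakpoints")
    if n_breaks == 0:
        return BreakpointFit(breakpoints=[], segment_slopes=[0.0],
                             rss=float(np.nansum((y - np.nanmean(y)) ** 2)))
    if n_breaks != 2:
        raise NotImplementedError("the segmented fit reports the two fork breakpoints")
    finite = y[np.isfinite(y)]
    const_rss = float(((finite - finite.mean()) ** 2).sum())
    if const_rss < 1e-12 or finite.max() - finite.min() < 0.05:
        return BreakpointFit(breakpoints=[], segment_slopes=[0.0], rss=const_rss,
                             fitted=np.full(n, finite.mean()))
    if anchor is None:
        anchor = int(np.nanargmax(y))
    ter = int(np.nanargmin(y))
    baseline = float(np.quantile(finite, 0.05))
    arc_cw = (np.arange(0, (ter - anchor) % n + 1) + anchor) % n
    arc_ccw = (anchor - np.arange(0, (anchor - ter) % n + 1)) % n
    feet, slopes_all, rss_total = [], [], 0.0
    fitted = np.full(n, np.nan)
    for arc in (arc_cw, arc_ccw):
        yv = y[arc]
        ok = np.isfinite(yv)
        x = np.arange(len(arc), dtype=float)
        foot, slopes, rss, fit_vals = _arc_foot(x[ok], yv[ok], baseline)
        # foot is an index into the compacted arc; map back to genome bins
        foot_bin = int(arc[np.flatnonzero(ok)[foot]])
        feet.append(foot_bin)
        slopes_all.extend(slopes)
        rss_total += rss
        fitted[arc[ok]] = fit_vals
    bp = sorted(int(b * mf.bin_size + mf.bin_size // 2) for b in feet)
    return BreakpointFit(breakpoints=bp, segment_slopes=slopes_all,
                         rss=rss_total, knots=feet, fitted=fitted)


def fork_distances(breakpoints, oriC: int, genome_length: int) -> tuple[int, int]:
    """Arc distances (bp) from oriC to two fork breakpoints, one per replichore.

    Each breakpoint is assigned to the replichore on which it is nearer to
    oriC; an error is raised when both fall on the same replichore.
    """
    if len(breakpoints) != 2:
        raise ValueError("exactly two breakpoints required")
    arms, dists = [], []
    for b in breakpoints:
        d_cw = (b - oriC) % genome_length
        d_ccw = (oriC - b) % genome_length
        if d_cw <= d_ccw:
            arms.append("cw")
            dists.append(d_cw)
        else:
            arms.append("ccw")
            dists.append(d_ccw)
    if arms[0] == arms[1] and dists != [0, 0]:
        raise ValueError("both breakpoints fall on the same replichore")
    cw = dists[arms.index("cw")] if "cw" in arms else 0
    ccw = dists[arms.index("ccw")] if "ccw" in arms else 0
    return int(cw), int(ccw)


def _occupancy_window(params: CometModelParams) -> float:
    """Total occupancy time per replication event, capped at one generation."""
    tau = params.comet_len / params.fork_speed + params.persistence
    if tau > params.T:
        warnings.warn("occupancy window exceeds one doubling time; capped at T")
        tau = params.T
    return tau


def simulate_comet_occupancy(params: CometModelParams, n_bins: int = 200):
    """Analytic steady-state occupancy O(s) and dosage D(s) per replichore bin.

    Returns ``(s, O, D)`` with ``s`` the replichore coordinate grid (bp,
    ori -> ter).  O(s) is the expected number of locus copies currently
    inside an occupancy window (comet or persistence), averaged over the
    exponential steady-state age distribution.
    """
    p = params
    if p.comet_len > p.L:
        warnings.warn("comet longer than the replichore; clipped")
        p = CometModelParams(**{**p.__dict__, "comet_len": p.L})
    s = np.linspace(0, p.L, n_bins)
    tau = _occupancy_window(p)
    D = 2.0 ** ((p.C + p.D - s / p.fork_speed) / p.T)
    O = 2.0 * (1.0 - 2.0 ** (-tau / p.T)) * D
    return s, O, D


def monte_carlo_comet(params: CometModelParams, n_cells: int = 100_000,
                      seed: int = 0, n_bins: int = 200):
    """Monte-Carlo oracle for the comet model.

    Cells are drawn from the steady-state age distribution; for each cell
    the replication history of every grid locus is reconstructed (how many
    completed replications it has seen, and the time since the most recent
    one) and occupied copies are counted mechanistically: a replication
    event marks both sister copies for ``tau`` minutes; at division the
    sisters separate, each daughter keeping one still-marked copy until the
    window expires.

    Returns ``(s, O_mc, stderr)``.
    """
    p = params
    rng = np.random.default_rng(seed)
    tau = _occupancy_window(p)
    u = rng.random(n_cells)
    ages = -p.T * np.log2(1.0 - u / 2.0)   # inverse CDF of f(a)
    s = np.linspace(0, p.L, n_bins)
    # lineage phase of the locus: total exponent and age at which it doubles
    expo = (p.C + p.D - s / p.fork_speed) / p.T
    m = np.floor(expo).astype(int)         # completed doublings carried as baseline
    a_star = p.T * (1.0 - (expo - m))      # age at which the next doubling happens
    occ = np.zeros((n_cells, n_bins))
    a = ages[:, None]
    this_gen = (a >= a_star) & (a < np.minimum(a_star + tau, p.T))
    prev_gen = a < (a_star + tau - p.T)
    occ = (2.0 * this_gen + 1.0 * prev_gen) * (2.0**m)
    O_mc = occ.mean(axis=0)
    stderr = occ.std(axis=0, ddof=1) / np.sqrt(n_cells)
    return s, O_mc, stderr


def flatness_stat(occupancy: np.ndarray, dosage: np.ndarray) -> float:
    """Coefficient of variation of O/D; large values reject the comet model."""
    occupancy = np.asarray(occupancy, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if np.any(dosage <= 0):
        raise ValueError("dosage must be positive")
    ratio = occupancy / dosage
    mean = ratio.mean()
    if mean == 0:
        return 0.0
    return float(ratio.std() / mean)


class MarkerFrequencyResults:
    """Marker-frequency fit: the track, breakpoints and fork distances."""

    def __init__(self, track: MarkerFrequencyTrack, fit: BreakpointFit,
                 genome: GenomeSpec):
        self.track = track
        self.fit = fit
        self.genome = genome
        self.breakpoints = fit.breakpoints
        if len(fit.breakpoints) == 2:
            self.fork_distances_bp = fork_distances(fit.breakpoints, genome.oriC,
                                                    genome.length)
        else:
            self.fork_distances_bp = None

    def summary(self) -> str:
        lines = [
            "Marker-frequency analysis",
            "=========================",
            f"bin size (bp)     : {self.track.bin_size}",
            f"fully replicated  : {self.track.fully_replicated}",
            f"breakpoints (bp)  : {self.breakpoints}",
            f"fit rss           : {self.fit.rss:.4g}",
        ]
        if self.fork_distances_bp is not None:
            cw, ccw = self.fork_distances_bp
            lines.append(f"fork travel (kb)  : {cw / 1000:.0f} (cw), {ccw / 1000:.0f} (ccw)")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        x = np.arange(len(self.track)) * self.track.bin_size
        ax.plot(x, self.track.values, ".", ms=2, label="marker frequency")
        if self.fit.fitted is not None:
            ax.plot(x, self.fit.fitted, "-", label="piecewise-linear fit")
        for b in self.breakpoints:
            ax.axvline(b, color="r", ls="--", lw=0.8)
        ax.set_xlabel("genome position (bp)")
        ax.set_ylabel("relative copy number")
        ax.legend(fontsize=8)
        return ax


class MarkerFrequencyModel:
    """Marker-frequency analysis as a model over sample/reference coverage."""

    def __init__(self, sample: StrandedProfile, reference: StrandedProfile,
                 genome: GenomeSpec, bin_size: int = 10_000):
        self.sample = sample
        self.reference = reference
        self.genome = genome
        self.bin_size = bin_size

    def fit(self, n_breaks: int = 2) -> MarkerFrequencyResults:
        track = marker_frequency(self.sample, self.reference, self.bin_size)
        # anchor the fit at the origin, a slope change known a priori
        anchor = self.genome.oriC // self.bin_size
        fit = detect_slope_breaks(track, n_breaks=n_breaks, anchor=anchor)
        return MarkerFrequencyResults(track, fit, self.genome)


class CometModel:
    """Replication-coupled occupancy null model (analytic + Monte-Carlo)."""

    def __init__(self, params: CometModelParams = CometModelParams()):
        self.params = params

    def occupancy(self, n_bins: int = 200):
        return simulate_comet_occupancy(self.params, n_bins)

    def monte_carlo(self, n_cells: int = 100_000, seed: int = 0, n_bins: int = 200):
        return monte_carlo_comet(self.params, n_cells, seed, n_bins)

    def flatness(self, n_bins: int = 200) -> float:
        _, O, D = self.occupancy(n_bins)
        return flatness_stat(O, D)
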
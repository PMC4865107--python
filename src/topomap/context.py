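"""Genomic-context statistics for called sites.

Relates a list of site positions to genome annotation: spacing between
consecutive sites, density along the genome, localization inside genes vs
intergenic regions, proximity to highly expressed transcription units,
gene-level overlap enrichment (Fisher's exact test), positional
dinucleotide profiles and GATC-motif spacing.  Random site sets drawn from
the same genome serve as controls throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec
from .synthetic import AnnotationSet  # noqa: F401  (re-exported container)

__all__ = [
    "AnnotationSet",
    "ContextParams",
    "consecutive_distances",
    "site_density",
    "gene_localization",
    "tu_proximity",
    "overlap_fisher",
    "dinucleotide_profile",
    "gatc_spacing",
    "random_sites",
]


@dataclass(frozen=True)
class ContextParams:
    expr_threshold: float = 500.0
    tu_distance_cut: int = 2_000
    fis_distance_cut: int = 400
    gatc_k: int = 20
    density_bin: int = 50_000

    def __post_init__(self):
        if min(self.expr_threshold, self.tu_distance_cut, self.fis_distance_cut,
               self.gatc_k, self.density_bin) <= 0:
            raise ValueError("all context parameters must be positive")


def consecutive_distances(sites, region: tuple[int, int]) -> dict:
    """Distances between adjacent sites inside [a, b) (linear, no wrap)."""
    a, b = region
    pos = np.sort(np.asarray([s for s in sites if a <= s < b], dtype=int))
    if len(pos) < 2:
        return {"distances": np.array([], dtype=int), "mean": np.nan, "median": np.nan}
    d = np.diff(pos)
    return {"distances": d, "mean": float(d.mean()), "median": float(np.median(d))}


def site_density(sites, genome: GenomeSpec, bin: int = 50_000) -> np.ndarray:
    """Histogram of site midpoints per circular bin (total = site count)."""
    n_bins = int(np.ceil(genome.length / bin))
    pos = np.asarray(sites, dtype=int) % genome.length
    return np.bincount(pos // bin, minlength=n_bins)


def gene_localization(sites, genes: pd.DataFrame) -> dict:
    """Classify site midpoints as genic or intergenic.

    Genic sites get a position normalized to the gene length and oriented
    5'->3' by strand (0 = gene start, 1 = gene end).  Fractions sum to 1.
    """
    pos = np.asarray(sites, dtype=int)
    if len(pos) == 0:
        return {"frac_in_genes": np.nan, "frac_intergenic": np.nan,
                "normalized_positions": np.array([])}
    g = genes.sort_values("start").reset_index(drop=True)
    starts = g["start"].to_numpy()
    ends = g["end"].to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(g) - 1)])
    norm = []
    for p, i in zip(pos[inside], idx[inside]):
        x = (p - starts[i]) / (ends[i] - starts[i])
        if g["strand"].iloc[i] == "-":
            x = 1.0 - x
        norm.append(x)
    frac_genic = inside.mean()
    return {
        "frac_in_genes": float(frac_genic),
        "frac_intergenic": float(1.0 - frac_genic),
        "normalized_positions": np.asarray(norm),
    }


def _distance_to_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                           length: int) -> np.ndarray:
    """Circular distance from each position to the nearest interval (0 inside)."""
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    out = np.empty(len(pos), dtype=float)
    for k, p in enumerate(pos):
        inside = (p >= starts) & (p < ends)
        if inside.any():
            out[k] = 0.0
            continue
        d_start = np.minimum((starts - p) % length, (p - starts) % length)
        d_end = np.minimum((ends - 1 - p) % length, (p - ends + 1) % length)
        out[k] = min(d_start.min(), d_end.min())
    return out


def tu_proximity(
    sites,
    tus: pd.DataFrame,
    expr_threshold: float = 500.0,
    random_control: tuple[int, int] | None = None,
    genome: GenomeSpec | None = None,
    tu_distance_cut: int = 2_000,
    test: str = "anova",
) -> dict:
    """Distance of each site to the nearest highly expressed TU, vs a random control.

    ``random_control=(n, seed)`` draws the control set; n defaults to the
    number of sites when 0 is given.  The two distance samples are compared
    with a one-way ANOVA F-test (``test="ranksum"`` switches to the
    rank-based Mann-Whitney alternative for the skew-robust variant).
    """
    if genome is None:
        raise ValueError("genome required for circular distances")
    hot = tus[tus["expression"] >= expr_threshold]
    if len(hot) == 0:
        raise ValueError(f"no TU above the expression threshold {expr_threshold}")
    pos = np.asarray(sites, dtype=int) % genome.length
    starts = hot["start"].to_numpy()
    ends = hot["end"].to_numpy()
    dist = _distance_to_intervals(pos, starts, ends, genome.length)
    out = {
        "distances": dist,
        "median": float(np.median(dist)) if len(dist) else np.nan,
        "frac_within_cut": float((dist <= tu_distance_cut).mean()) if len(dist) else np.nan,
    }
    if random_control is not None:
        n, seed = random_control
        n = n or len(pos)
        ctrl = random_sites(n, genome, seed)
        cdist = _distance_to_intervals(ctrl, starts, ends, genome.length)
        if test == "anova":
            stat, p = stats.f_oneway(dist, cdist)
        elif test == "ranksum":
            stat, p = stats.mannwhitneyu(dist, cdist, alternative="two-sided")
        else:
            raise ValueError("test must be 'anova' or 'ranksum'")
        out.update({"control_distances": cdist, "control_median": float(np.median(cdist)),
                    "statistic": float(stat), "p_value": float(p)})
    return out


def overlap_fisher(sites, features: pd.DataFrame, genes: pd.DataFrame) -> dict:
    """Gene-level overlap enrichment between sites and a feature set.

    Each gene is labelled by whether it carries a site midpoint and whether
    it overlaps a feature interval; the one-sided (enrichment) Fisher exact
    p-value of the 2x2 table is returned together with the common/total
    feature-gene counts.
    """
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    g = genes.sort_values("start").reset_index(drop=True)
    starts = g["start"].to_numpy()
    ends = g["end"].to_numpy()
    pos = np.sort(np.asarray(sites, dtype=int))
    has_site = np.zeros(len(g), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(g) - 1)])
    has_site[idx[ok]] = True
    has_feat = np.zeros(len(g), dtype=bool)
    if {"start", "end"}.issubset(features.columns):
        f_starts = features["start"].to_numpy()
        f_ends = features["end"].to_numpy()
    else:  # point features
        f_starts = features.iloc[:, 0].to_numpy()
        f_ends = f_starts + 1
    for fs, fe in zip(f_starts, f_ends):
        has_feat |= (starts < fe) & (ends > fs)
    table = np.array([
        [int((has_site & has_feat).sum()), int((has_site & ~has_feat).sum())],
        [int((~has_site & has_feat).sum()), int((~has_site & ~has_feat).sum())],
    ])
    _, p = stats.fisher_exact(table, alternative="greater")
    return {
        "n_common_genes": int(table[0, 0]),
        "n_feature_genes": int(has_feat.sum()),
        "n_site_genes": int(has_site.sum()),
        "table": table,
        "p_value": float(p),
    }


def dinucleotide_profile(
    genome: GenomeSpec,
    sites,
    window: int = 200,
    dinucleotide: str = "GC",
) -> np.ndarray:
    """Frequency of a dinucleotide at each offset around the site centers.

    Offsets run over [-window/2, window/2); the dinucleotide is counted on
    the forward strand at the position where it starts (circular wrap).
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required")
    if len(dinucleotide) != 2:
        raise ValueError("dinucleotide must have length 2")
    seq = genome.sequence
    ext = seq + seq[:window + 2]
    pos = np.asarray(sites, dtype=int) % genome.length
    offsets = np.arange(-window // 2, window // 2)
    counts = np.zeros(len(offsets))
    for p in pos:
        for k, o in enumerate(offsets):
            q = (p + o) % genome.length
            if ext[q:q + 2] == dinucleotide:
                counts[k] += 1
    return counts / max(len(pos), 1)


def gatc_spacing(
    genome: GenomeSpec,
    sites,
    k: int = 20,
    random_control: tuple[int, int] | None = None,
) -> dict:
    """Mean distance between consecutive GATC motifs around the sites.

    For each site the 2k+1 GATC occurrences flanking it (k on each side plus
    the nearest) are located on the circular genome and the 2k consecutive
    spacings are recorded by rank (-k .. k-1, negative ranks upstream of the
    site).  Means are taken over sites; a random control set of equal size is
    processed identically when ``random_control=(n, seed)`` is given.
    """
    if genome.sequence is None:
        raise ValueError("genome sequence required")
    motif_pos = np.array([m.start() for m in re.finditer("GATC", genome.sequence)])
    n_motifs = len(motif_pos)
    if n_motifs < 2 * k + 2:
        raise ValueError("sequence contains too few GATC motifs")

    def spacings_for(pos_list):
        ranks = np.arange(-k, k)
        acc = np.zeros(2 * k)
        cnt = 0
        skipped = 0
        ext = np.concatenate([motif_pos - genome.length, motif_pos, motif_pos + genome.length])
        ext.sort()
        for p in pos_list:
            i = np.searchsorted(ext, p)
            lo, hi = i - k, i + k + 1
            if lo < 0 or hi > len(ext):
                skipped += 1
                continue
            flank = ext[lo:hi]
            acc += np.diff(flank)
            cnt += 1
        mean = acc / cnt if cnt else np.full(2 * k, np.nan)
        return ranks, mean, skipped

    pos = np.asarray(sites, dtype=int) % genome.length
    ranks, site_mean, site_skipped = spacings_for(pos)
    out = {"ranks": ranks, "site_mean_spacing": site_mean, "n_sites_skipped": site_skipped}
    if random_control is not None:
        n, seed = random_control
        n = n or len(pos)
        ctrl = random_sites(n, genome, seed)
        _, ctrl_mean, ctrl_skipped = spacings_for(ctrl)
        out.update({"control_mean_spacing": ctrl_mean, "n_control_skipped": ctrl_skipped})
    return out


def random_sites(
    n: int,
    genome: GenomeSpec,
    seed: int,
    exclusions: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Uniform random positions outside the excluded intervals (seeded)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.array([], dtype=int)
    if not exclusions:
        return rng.integers(0, genome.length, size=n)
    allowed = np.ones(genome.length, dtype=bool)
    for a, b in exclusions:
        idx = np.arange(a, b) % genome.length
        allowed[idx] = False
    pool = np.flatnonzero(allowed)
    if len(pool) == 0:
        raise ValueError("exclusions cover the whole genome")
    return pool[rng.integers(0, len(pool), size=n)]
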
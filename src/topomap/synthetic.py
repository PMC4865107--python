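"""Synthetic genomes, annotations and stranded coverage with planted truth.

The generator emulates the statistical structure the downstream analyses
assume, without simulating reads:

* cleavage (NorflIP-like) sites with the canonical strand-asymmetric
  geometry -- a ~170 bp forward-strand enrichment block and a ~170 bp
  reverse-strand block separated by a ~130 bp non-enriched gap, with a
  ~100 bp central window where raw read rates drop to zero because the
  covalently trapped topoisomerase blocks ligation of the cleaved 5' ends;
* symmetric ~200 bp binding (ChIP-like) peaks on both strands;
* artifact regions (rRNA-like, tRNA-like, IS-like) that enrich the IP *and*
  the mock IP but not the input;
* replication gene-dosage gradients (asynchronous steady state, or
  synchronized fork pairs);
* uniform Poisson background and input.

The read model is a per-base Poisson rate; ``noise=False`` returns the rate
tracks themselves so geometric assertions are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec, replichore_coordinate
from .profiles import StrandedProfile

__all__ = [
    "ShapeParams",
    "PlantedSite",
    "ArtifactRegion",
    "SyntheticExperiment",
    "make_genome",
    "plant_norflip_experiment",
    "plant_chip_experiment",
    "add_artifacts",
    "make_dosage_track",
    "make_annotation",
    "DEFAULT_DEPTH",
    "MIN_SITE_SPACING",
]

#: default sequencing depth (reads per bp per strand) for IP background and input
DEFAULT_DEPTH = 5.0
#: planted sites closer than this are flagged (template interference)
MIN_SITE_SPACING = 2_000


@dataclass(frozen=True)
class ShapeParams:
    """Canonical cleavage-site geometry (all spans in bp)."""

    fwd_span: int = 170
    rev_span: int = 170
    gap: int = 130
    read_depletion: int = 100
    fragment_len: int = 250
    peak_fold: float = 10.0

    def __post_init__(self):
        if min(self.fwd_span, self.rev_span, self.gap, self.fragment_len) <= 0:
            raise ValueError("all spans must be positive")
        if self.gap < self.read_depletion:
            raise ValueError("gap must be >= read_depletion")

    @property
    def footprint(self) -> int:
        return self.fwd_span + self.gap + self.rev_span


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record for one planted site."""

    center: int
    kind: str = "cleavage"  # or "binding"
    fold: float = 10.0

    def __post_init__(self):
        if self.kind not in ("cleavage", "binding"):
            raise ValueError("kind must be 'cleavage' or 'binding'")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")


@dataclass(frozen=True)
class ArtifactRegion:
    """Non-specific signal shared between the IP and the mock IP."""

    start: int
    end: int
    fold: float
    label: str = "rRNA-like"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("artifact interval must satisfy start < end")
        if self.fold <= 1:
            raise ValueError("artifact fold must be > 1")


@dataclass
class SyntheticExperiment:
    """One simulated IP / input / mock triplet with its ground truth."""

    ip: StrandedProfile
    input: StrandedProfile
    mock: StrandedProfile
    truth: list[PlantedSite]
    genome: GenomeSpec
    artifacts: list[ArtifactRegion] = field(default_factory=list)
    seed: int = 0
    noise: bool = True
    warnings: list[str] = field(default_factory=list)


def make_genome(
    length: int,
    oriC: int | None = None,
    dif: int | None = None,
    gc_fraction: float = 0.5,
    seed: int = 0,
    with_sequence: bool = True,
) -> GenomeSpec:
    """Random i.i.d. genome at the given GC fraction, MG1655-like landmarks.

    ``with_sequence=False`` skips sequence generation for coverage-only
    simulations on multi-Mb genomes.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    if with_sequence:
        p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
        codes = rng.choice(np.frombuffer(b"AGCT", dtype=np.uint8), size=length, p=p)
        seq = codes.tobytes().decode()
    else:
        seq = None
    base = GenomeSpec.ecoli_like(length)
    return GenomeSpec(
        length=length,
        oriC=base.oriC if oriC is None else oriC,
        dif=base.dif if dif is None else dif,
        sequence=seq,
    )


def _check_sites(genome: GenomeSpec, sites, footprint: int) -> list[str]:
    notes = []
    centers = sorted(s.center for s in sites)
    for s in sites:
        if not 0 <= s.center < genome.length:
            raise ValueError(f"site center {s.center} outside genome")
    if len(set(centers)) != len(centers):
        raise ValueError("planted site centers must be unique")
    for a, b in zip(centers, centers[1:]):
        if b - a < footprint:
            notes.append(f"sites at {a} and {b} overlap (spacing {b - a} < {footprint})")
        elif b - a < MIN_SITE_SPACING:
            notes.append(f"sites at {a} and {b} closer than {MIN_SITE_SPACING} bp")
    return notes


def _paint(rate: np.ndarray, start: int, stop: int, value: float, mode: str = "mul"):
    """Assign/scale a circular [start, stop) window of a rate track."""
    n = len(rate)
    idx = np.arange(start, stop) % n
    if mode == "mul":
        rate[idx] *= value
    else:
        rate[idx] = value


def _poisson(rng, rate: np.ndarray, base: float) -> np.ndarray:
    """Poisson draw; the constant baseline uses a scalar rate (much faster)."""
    out = rng.poisson(base, size=len(rate)).astype(float)
    idx = np.flatnonzero(rate != base)
    if len(idx):
        out[idx] = rng.poisson(rate[idx])
    return out


def _finish(fwd_rate, rev_rate, genome, rng, noise, base) -> StrandedProfile:
    if noise:
        fwd = _poisson(rng, fwd_rate, base)
        rev = _poisson(rng, rev_rate, base)
    else:
        fwd, rev = fwd_rate.copy(), rev_rate.copy()
    return StrandedProfile(fwd=fwd, rev=rev, genome=genome)


def _finish_const(rate: float, genome, rng, noise) -> StrandedProfile:
    if noise:
        fwd = rng.poisson(rate, size=genome.length).astype(float)
        rev = rng.poisson(rate, size=genome.length).astype(float)
    else:
        fwd = np.full(genome.length, float(rate))
        rev = np.full(genome.length, float(rate))
    return StrandedProfile(fwd=fwd, rev=rev, genome=genome)


def plant_norflip_experiment(
    genome: GenomeSpec,
    sites: list[PlantedSite],
    shape: ShapeParams = ShapeParams(),
    depth: float = DEFAULT_DEPTH,
    bg_rate: float = DEFAULT_DEPTH,
    seed: int = 0,
    noise: bool = True,
) -> SyntheticExperiment:
    """Plant strand-asymmetric cleavage sites in an IP/input/mock triplet.

    For a site centered at ``c`` the forward-strand rate is elevated by the
    site's fold on ``[c - gap/2 - fwd_span, c - gap/2)``, the reverse rate on
    ``[c + gap/2, c + gap/2 + rev_span)``, and both raw rates drop to zero on
    the central ``read_depletion`` window (ligation of the covalently bound
    5' ends fails, so the cleaved extremities are almost never sequenced).
    The input is uniform at ``depth`` per strand; the mock is background-only.
    """
    if depth <= 0 or bg_rate <= 0:
        raise ValueError("depth and bg_rate must be positive")
    notes = _check_sites(genome, sites, shape.footprint)
    rng = np.random.default_rng(seed)
    L = genome.length
    fwd = np.full(L, float(bg_rate))
    rev = np.full(L, float(bg_rate))
    for s in sites:
        c = s.center
        half_gap = shape.gap // 2
        _paint(fwd, c - half_gap - shape.fwd_span, c - half_gap, s.fold, "mul")
        _paint(rev, c + shape.gap - half_gap, c + shape.gap - half_gap + shape.rev_span, s.fold, "mul")
        d0 = c - shape.read_depletion // 2
        _paint(fwd, d0, d0 + shape.read_depletion, 0.0, "set")
        _paint(rev, d0, d0 + shape.read_depletion, 0.0, "set")
    ip = _finish(fwd, rev, genome, rng, noise, float(bg_rate))
    inp = _finish_const(float(depth), genome, rng, noise)
    mock = _finish_const(float(bg_rate), genome, rng, noise)
    return SyntheticExperiment(
        ip=ip, input=inp, mock=mock,
        truth=sorted(sites, key=lambda s: s.center), genome=genome,
        seed=seed, noise=noise, warnings=notes,
    )


def plant_chip_experiment(
    genome: GenomeSpec,
    sites: list[PlantedSite],
    span: int = 200,
    depth: float = DEFAULT_DEPTH,
    bg_rate: float = DEFAULT_DEPTH,
    seed: int = 0,
    noise: bool = True,
) -> SyntheticExperiment:
    """Plant symmetric binding peaks: both strands elevated over ``span`` bp."""
    if depth <= 0 or bg_rate <= 0:
        raise ValueError("depth and bg_rate must be positive")
    notes = _check_sites(genome, sites, span)
    rng = np.random.default_rng(seed)
    L = genome.length
    fwd = np.full(L, float(bg_rate))
    rev = np.full(L, float(bg_rate))
    for s in sites:
        a = s.center - span // 2
        _paint(fwd, a, a + span, s.fold, "mul")
        _paint(rev, a, a + span, s.fold, "mul")
    ip = _finish(fwd, rev, genome, rng, noise, float(bg_rate))
    inp = _finish_const(float(depth), genome, rng, noise)
    mock = _finish_const(float(bg_rate), genome, rng, noise)
    return SyntheticExperiment(
        ip=ip, input=inp, mock=mock,
        truth=sorted(sites, key=lambda s: s.center), genome=genome,
        seed=seed, noise=noise, warnings=notes,
    )


def add_artifacts(exp: SyntheticExperiment, regions: list[ArtifactRegion]) -> SyntheticExperiment:
    """Multiply IP *and* mock signal by each region's fold (input unchanged)."""
    if not regions:
        return exp
    ip_f, ip_r = exp.ip.fwd.copy(), exp.ip.rev.copy()
    mo_f, mo_r = exp.mock.fwd.copy(), exp.mock.rev.copy()
    for reg in regions:
        if not (0 <= reg.start < exp.genome.length) or reg.end > exp.genome.length:
            raise ValueError(f"artifact region [{reg.start}, {reg.end}) outside genome")
        for arr in (ip_f, ip_r, mo_f, mo_r):
            arr[reg.start:reg.end] *= reg.fold
    return replace(
        exp,
        ip=StrandedProfile(fwd=ip_f, rev=ip_r, genome=exp.genome),
        mock=StrandedProfile(fwd=mo_f, rev=mo_r, genome=exp.genome),
        artifacts=list(exp.artifacts) + list(regions),
    )


def make_dosage_track(
    genome: GenomeSpec,
    doubling_time: float | None = None,
    C_period: float | None = None,
    forks: tuple[int, int] | None = None,
    front_width: int = 0,
) -> np.ndarray:
    """Per-position relative copy-number (gene dosage) track.

    Asynchronous steady state (give ``doubling_time`` T and ``C_period`` C):
    a locus a fraction ``f`` of the way down its replichore has relative
    dosage ``2**(C*(1-f)/T)``, normalized to 1 at the terminus, so the
    ori:ter ratio is ``2**(C/T)``.

    Synchronized state (give ``forks=(pos_cw, pos_ccw)``): dosage is 2 on the
    arcs already replicated (oriC out to each fork) and 1 beyond.
    ``front_width`` adds a linear ramp of that many bp at each fork front,
    emulating fork-position dispersion across the population.
    """
    L = genome.length
    pos = np.arange(L)
    dist, arm = replichore_coordinate(genome, pos)
    if forks is not None:
        if doubling_time is not None or C_period is not None:
            raise ValueError("give either forks or (doubling_time, C_period), not both")
        d_cw = (forks[0] - genome.oriC) % L
        d_ccw = (genome.oriC - forks[1]) % L
        cw_span = (genome.dif - genome.oriC) % L
        ccw_span = (genome.oriC - genome.dif) % L
        if d_cw > cw_span or d_ccw > ccw_span:
            raise ValueError("fork positions beyond the terminus")
        travelled = np.where(arm == 1, d_cw, d_ccw)
        if front_width > 0:
            # ramp from 2 at (travelled - front_width) down to 1 at the front
            track = 1.0 + np.clip((travelled - dist) / front_width, 0.0, 1.0)
        else:
            track = np.where(dist <= travelled, 2.0, 1.0)
        return track
    if doubling_time is None or C_period is None:
        raise ValueError("need doubling_time and C_period for the asynchronous state")
    cw_span = (genome.dif - genome.oriC) % L
    ccw_span = (genome.oriC - genome.dif) % L
    span = np.where(arm == 1, cw_span, ccw_span)
    f = dist / np.maximum(span, 1)
    return 2.0 ** (C_period * (1.0 - f) / doubling_time)


@dataclass
class AnnotationSet:
    """Genes, transcription units with expression, Fis sites, H-NS regions."""

    genes: pd.DataFrame      # columns: start, end, strand, name
    tus: pd.DataFrame        # columns: start, end, expression
    fis_sites: np.ndarray    # point positions
    hns_regions: pd.DataFrame  # columns: start, end
    genome: GenomeSpec | None = None

    @property
    def intergenic_fraction(self) -> float:
        if self.genome is None:
            raise ValueError("annotation has no genome attached")
        covered = int((self.genes["end"] - self.genes["start"]).sum())
        return 1.0 - covered / self.genome.length


def make_annotation(
    genome: GenomeSpec,
    n_genes: int = 400,
    n_tus_highly_expressed: int = 40,
    n_fis: int = 200,
    n_hns_regions: int = 30,
    seed: int = 0,
    gene_fraction: float = 0.85,
    expr_threshold: float = 500.0,
) -> AnnotationSet:
    """Random non-overlapping genes, heavy-tailed TU expression, Fis/H-NS.

    Genes cover ``gene_fraction`` of the genome (E. coli is ~88% genic).
    TUs reuse the gene intervals; ``n_tus_highly_expressed`` of them get
    expression drawn uniformly in [threshold, 30000] reads (a realistic
    RNA-seq read-count range for bacterial TUs), the rest fall below the
    threshold on a log-normal tail.
    """
    rng = np.random.default_rng(seed)
    L = genome.length
    if n_genes == 0:
        genes = pd.DataFrame(columns=["start", "end", "strand", "name"])
        tus = pd.DataFrame(columns=["start", "end", "expression"])
    else:
        if not 0 < gene_fraction < 1:
            raise ValueError("gene_fraction must be in (0, 1)")
        total_genic = int(gene_fraction * L)
        if total_genic < n_genes:
            raise ValueError("cannot pack that many genes into the genome")
        w = rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
        lengths = np.maximum(1, np.round(w / w.sum() * total_genic).astype(int))
        drift = total_genic - lengths.sum()
        lengths[0] = max(1, lengths[0] + drift)
        gap_total = L - lengths.sum()
        if gap_total < 0:
            raise ValueError("infeasible gene packing")
        g = rng.exponential(size=n_genes)
        gaps = np.floor(g / g.sum() * gap_total).astype(int)
        starts = np.zeros(n_genes, dtype=int)
        cursor = 0
        for i in range(n_genes):
            starts[i] = cursor
            cursor += lengths[i] + gaps[i]
        ends = starts + lengths
        if ends[-1] > L:
            raise ValueError("infeasible gene packing")
        strands = rng.choice(["+", "-"], size=n_genes)
        genes = pd.DataFrame(
            {"start": starts, "end": ends, "strand": strands,
             "name": [f"gene{i:04d}" for i in range(n_genes)]}
        )
        if n_tus_highly_expressed > n_genes:
            raise ValueError("more highly expressed TUs than genes")
        expr = np.minimum(rng.lognormal(mean=3.0, sigma=1.5, size=n_genes), expr_threshold - 1)
        hot = rng.choice(n_genes, size=n_tus_highly_expressed, replace=False)
        expr[hot] = rng.uniform(expr_threshold, 30_000, size=n_tus_highly_expressed)
        tus = pd.DataFrame({"start": starts, "end": ends, "expression": expr})
    fis = np.sort(rng.integers(0, L, size=n_fis)) if n_fis else np.array([], dtype=int)
    if n_hns_regions:
        h_starts = np.sort(rng.integers(0, L, size=n_hns_regions))
        h_lens = rng.integers(2_000, 10_000, size=n_hns_regions)
        hns = pd.DataFrame({"start": h_starts, "end": np.minimum(h_starts + h_lens, L)})
    else:
        hns = pd.DataFrame(columns=["start", "end"])
    return AnnotationSet(genes=genes, tus=tus, fis_sites=fis, hns_regions=hns, genome=genome)
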
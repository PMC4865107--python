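"""Template Pearson-correlation scanning over circular tracks (internal).

The scan computes, for every window start ``p`` (at a fixed step), the
Pearson correlation between a fixed template of length ``w`` and the track
values on the circular window ``[p, p + w)``.  FFT cross-correlation plus
prefix sums make the full-genome scan O(L log L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["pearson_scan", "merge_hits", "Candidate"]


@dataclass(frozen=True)
class Candidate:
    """One merged scan hit: window center and its correlation."""

    center: int
    r: float
    window_start: int


def pearson_scan(track: np.ndarray, template: np.ndarray, step: int = 100):
    """Correlation of ``template`` with every circular window at ``step`` bp.

    Returns ``(starts, r)`` where ``starts`` are window start positions and
    ``r`` the Pearson correlation of the template with the window values.
    Constant windows get r = 0 by convention (they cannot match a structured
    template).
    """
    track = np.asarray(track, dtype=float)
    template = np.asarray(template, dtype=float)
    L, w = len(track), len(template)
    if w >= L:
        raise ValueError("template must be shorter than the track")
    t = template - template.mean()
    t_norm = np.sqrt((t**2).sum())
    if t_norm == 0:
        raise ValueError("template is constant")
    # circular cross-correlation: c[p] = sum_k t[k] * track[(p + k) % L],
    # computed as a linear correlation on the wrapped-extended track so the
    # FFT length can be padded to a fast size regardless of L's factors
    ext = np.concatenate([track, track[:w]])
    c = signal.fftconvolve(ext, t[::-1], mode="valid")[:L]
    cs1 = np.concatenate([[0.0], np.cumsum(ext)])
    cs2 = np.concatenate([[0.0], np.cumsum(ext**2)])
    starts = np.arange(0, L, step)
    s1 = cs1[starts + w] - cs1[starts]
    s2 = cs2[starts + w] - cs2[starts]
    var = s2 - s1**2 / w
    # numerator: t is centered, so sum(t * x) already equals sum(t * (x - xbar))
    num = c[starts]
    den = t_norm * np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 1e-12 * t_norm, num / np.maximum(den, 1e-300), 0.0)
    return starts, np.clip(r, -1.0, 1.0)


def merge_hits(
    starts: np.ndarray,
    r: np.ndarray,
    window: int,
    r_min: float,
    merge_distance: int,
    genome_length: int,
) -> list[Candidate]:
    """Threshold the scan at ``r_min`` and merge nearby hits.

    Hits whose window centers lie within ``merge_distance`` of each other are
    clustered (circularly); each cluster keeps its maximum-correlation
    window, ties broken toward the smaller coordinate.  Negative correlations
    are never hits.
    """
    sel = r >= r_min
    if not sel.any():
        return []
    pos = starts[sel]
    rv = r[sel]
    centers = (pos + window // 2) % genome_length
    order = np.argsort(centers)
    centers, pos, rv = centers[order], pos[order], rv[order]
    gaps = np.diff(centers)
    breaks = np.flatnonzero(gaps > merge_distance) + 1
    clusters = np.split(np.arange(len(centers)), breaks)
    # circular wrap: first and last cluster may be one
    if len(clusters) > 1:
        wrap_gap = centers[0] + genome_length - centers[-1]
        if wrap_gap <= merge_distance:
            clusters[0] = np.concatenate([clusters[-1], clusters[0]])
            clusters = clusters[:-1]
    out = []
    for idx in clusters:
        best = idx[np.argmax(rv[idx])]
        # tie-break toward smaller coordinate
        tied = idx[np.abs(rv[idx] - rv[best]) < 1e-12]
        best = tied[np.argmin(centers[tied])]
        out.append(Candidate(center=int(centers[best]), r=float(rv[best]),
                             window_start=int(pos[best])))
    out.sort(key=lambda cand: cand.center)
    return out
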
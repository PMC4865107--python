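"""Circular-genome coordinate conventions.

All coordinates in :mod:`topomap` are 0-based, half-open and BED-compatible.
Window arithmetic wraps circularly: position ``-10`` on a genome of length
``L`` is position ``L - 10``.  The two replichores are the arcs running from
*oriC* to the terminus (*dif*) clockwise (increasing coordinate) and
counter-clockwise (decreasing coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenomeSpec", "wrap", "take_circular", "arc_length", "replichore_coordinate"]

# MG1655-like relative positions used when only a length is given: oriC sits
# at ~84.6% of the map and dif at ~34.2% (so oriC and dif are nearly opposite).
_ORIC_FRACTION = 0.8462
_DIF_FRACTION = 0.3425


@dataclass(frozen=True)
class GenomeSpec:
    """A circular bacterial genome with its replication landmarks.

    Parameters
    ----------
    length : int
        Genome size in bp (> 0).
    oriC : int
        Position of the replication origin, ``0 <= oriC < length``.
    dif : int
        Position of the chromosome-dimer resolution site, opposite *oriC*.
    circular : bool
        Linear genomes are accepted but window arithmetic does not wrap.
    sequence : str, optional
        Upper-case nucleotide sequence of exactly ``length`` characters over
        {A, C, G, T}.
    """

    length: int
    oriC: int
    dif: int
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        for name in ("oriC", "dif"):
            pos = getattr(self, name)
            if not 0 <= pos < self.length:
                raise ValueError(
                    f"{name}={pos} outside genome [0, {self.length})"
                )
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != genome length {self.length}"
                )
            if set(self.sequence) - set("ACGT"):
                raise ValueError("sequence alphabet must be a subset of {A,C,G,T}")

    @classmethod
    def ecoli_like(cls, length: int = 4_639_000, sequence: str | None = None) -> "GenomeSpec":
        """A genome with oriC/dif at their MG1655-like relative positions."""
        return cls(
            length=length,
            oriC=int(round(_ORIC_FRACTION * length)),
            dif=int(round(_DIF_FRACTION * length)),
            sequence=sequence,
        )

    def wrap(self, pos: int | np.ndarray):
        return np.asarray(pos) % self.length if isinstance(pos, np.ndarray) else pos % self.length


def wrap(pos, length: int):
    """Map positions onto [0, length) circularly."""
    return np.asarray(pos) % length


def take_circular(values: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Slice ``values[start:stop]`` with circular wrap (stop may exceed len)."""
    n = len(values)
    if stop - start > n:
        raise ValueError("circular slice longer than the track")
    idx = np.arange(start, stop) % n
    return values[idx]


def arc_length(a: int, b: int, length: int, direction: str = "cw") -> int:
    """Arc distance from ``a`` to ``b`` on the circle.

    ``direction="cw"`` walks with increasing coordinate, ``"ccw"`` against it.
    """
    if direction == "cw":
        return (b - a) % length
    if direction == "ccw":
        return (a - b) % length
    raise ValueError("direction must be 'cw' or 'ccw'")


def replichore_coordinate(genome: GenomeSpec, positions) -> tuple[np.ndarray, np.ndarray]:
    """Distance of each position from oriC along its replichore.

    Returns ``(distance, arm)`` where ``arm`` is +1 for the clockwise
    replichore (oriC -> dif with increasing coordinate) and -1 for the
    counter-clockwise one.  The terminus is taken at *dif*.
    """
    pos = np.atleast_1d(np.asarray(positions)) % genome.length
    L = genome.length
    cw_span = (genome.dif - genome.oriC) % L  # length of the clockwise replichore
    d_cw = (pos - genome.oriC) % L
    on_cw = d_cw <= cw_span
    dist = np.where(on_cw, d_cw, (genome.oriC - pos) % L)
    arm = np.where(on_cw, 1, -1)
    return dist, arm
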
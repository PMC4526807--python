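"""Tonotopic grids.

The model lives on a one-dimensional tonotopic axis x measured in octaves.
Two topologies are supported:

* ``ring`` — one octave with periodic boundary, the natural space of Shepard
  tone pitch classes (12 semitones = 1 octave).  Default: 100 points,
  dx = 0.01 octave.
* ``line`` — a finite non-periodic axis for spectrally non-periodic stimuli
  (chords of pure tones); convolutions are zero-padded at the edges.

Pitch is expressed in semitones (st) at the API surface (1 st = 1/12 oct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TonotopicGrid", "ST_PER_OCT"]

ST_PER_OCT = 12.0


@dataclass(frozen=True)
class TonotopicGrid:
    """Discretized tonotopic axis.

    Parameters
    ----------
    topology : "ring" or "line".
    n : number of grid points.
    dx : grid spacing in octaves (default 0.01).
    x0 : line topology only — coordinate of the first grid point (octaves).
    """

    topology: str = "ring"
    n: int = 100
    dx: float = 0.01
    x0: float = 0.0

    def __post_init__(self):
        if self.topology not in ("ring", "line"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n < 4:
            raise ValueError("grid needs at least 4 points")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def extent(self) -> float:
        """Domain length in octaves (ring: circumference)."""
        return self.n * self.dx

    @property
    def x(self) -> np.ndarray:
        """Grid coordinates in octaves."""
        return self.x0 + self.dx * np.arange(self.n)

    @property
    def st(self) -> np.ndarray:
        """Grid coordinates in semitones."""
        return self.x * ST_PER_OCT

    def wrap(self, d: np.ndarray | float) -> np.ndarray | float:
        """Wrap displacements (octaves) to the principal interval.

        Ring: (-extent/2, extent/2]; line: identity.
        """
        if self.topology == "line":
            return d
        L = self.extent
        return -((-np.asarray(d) + L / 2.0) % L) + L / 2.0

    def distance(self, a: np.ndarray | float, b: np.ndarray | float):
        """Signed displacement a - b in octaves (ring: circular)."""
        return self.wrap(np.asarray(a, dtype=float) - b)

    def index_near(self, pitch_st: float) -> int:
        """Index of the grid point closest to a pitch (st)."""
        x = pitch_st / ST_PER_OCT
        if self.topology == "ring":
            return int(np.round((x - self.x0) / self.dx)) % self.n
        i = int(np.round((x - self.x0) / self.dx))
        if not 0 <= i < self.n:
            raise ValueError(f"pitch {pitch_st} st outside line grid")
        return i

    def contains(self, x_oct: float, margin: float = 0.0) -> bool:
        """True if an octave coordinate lies in the domain (line) with margin."""
        if self.topology == "ring":
            return True
        return self.x0 + margin <= x_oct <= self.x0 + (self.n - 1) * self.dx - margin

    @classmethod
    def ring(cls, n: int = 100, dx: float = 0.01) -> "TonotopicGrid":
        return cls("ring", n=n, dx=dx)

    @classmethod
    def line(cls, span_oct: float, dx: float = 0.01, x0: float = 0.0) -> "TonotopicGrid":
        """Line grid covering [x0, x0 + span_oct]."""
        n = int(np.round(span_oct / dx)) + 1
        return cls("line", n=n, dx=dx, x0=x0)
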
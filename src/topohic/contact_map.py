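"""The binned contact-matrix container and its sparse text dialect.

Matrices are stored dense (a bacterial genome at 2-10 kb bins is under a
thousand bins, so dense float64 is the right container).  The on-disk
dialect is plain text: ``#``-prefixed header lines carrying the genome
name/length, bin size, bin count, normalization state and mask, followed
by upper-triangle body rows ``bin_i<TAB>bin_j<TAB>value`` with i <= j.
Values are written with ``repr`` so the round trip is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genome import Genome

#: states a matrix can be in; "expected" marks noise-free simulator output,
#: which downstream comparison operations accept like a normalized map.
STATES = ("raw", "normalized", "expected")


def n_bins_for(length: int, bin_size: int) -> int:
    return math.ceil(length / bin_size)


@dataclass
class ContactMap:
    """Symmetric binned contact matrix for a single replicon.

    ``mask`` is a boolean vector (True = bin excluded); masked rows and
    columns are kept all-zero.  ``bin(pos) = pos // bin_size``; the last
    bin may be shorter than ``bin_size``.
    """

    genome: Genome
    bin_size: int
    values: np.ndarray
    mask: Optional[np.ndarray] = None
    state: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        n = n_bins_for(self.genome.length, self.bin_size)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} != ({n}, {n}) for length "
                f"{self.genome.length} at bin size {self.bin_size}")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError("mask length != n_bins")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos: int) -> int:
        if not 0 <= pos < self.genome.length:
            raise ValueError(f"position {pos} outside genome")
        return pos // self.bin_size

    def bins_in_span(self, span) -> np.ndarray:
        """Bin indices whose start falls in the half-open bp span (wrap-aware)."""
        start, end = span
        b0, b1 = start // self.bin_size, math.ceil(end / self.bin_size)
        if end >= start:
            return np.arange(b0, min(b1, self.n_bins))
        if not self.genome.circular:
            raise ValueError("wrapping span on a linear genome")
        return np.concatenate([np.arange(b0, self.n_bins), np.arange(0, b1)])

    def separation_bp(self, i, j) -> np.ndarray:
        """Genomic separation between bin indices, circular-aware, in bp."""
        d = np.abs(np.asarray(i) - np.asarray(j))
        if self.genome.circular:
            d = np.minimum(d, self.n_bins - d)
        return d * self.bin_size

    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def apply_mask(self) -> None:
        """Zero out masked rows and columns in place."""
        self.values[self.mask, :] = 0.0
        self.values[:, self.mask] = 0.0

    def copy(self) -> "ContactMap":
        return ContactMap(self.genome, self.bin_size, self.values.copy(),
                          self.mask.copy(), self.state, dict(self.meta))

    def check_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.values - self.values.T) <= tol))

    @property
    def total(self) -> float:
        """Total contact count: upper triangle plus diagonal (pairs counted once)."""
        return float(np.triu(self.values).sum())


def write_sparse(cmap: ContactMap, path: str) -> None:
    """Write the sparse upper-triangle text dialect (bit-exact round trip)."""
    with open(path, "w") as fh:
        fh.write("# topohic-matrix v1\n")
        fh.write(f"# genome: {cmap.genome.name}\n")
        fh.write(f"# length: {cmap.genome.length}\n")
        fh.write(f"# circular: {int(cmap.genome.circular)}\n")
        fh.write(f"# bin_size: {cmap.bin_size}\n")
        fh.write(f"# n_bins: {cmap.n_bins}\n")
        fh.write(f"# state: {cmap.state}\n")
        masked = np.flatnonzero(cmap.mask)
        fh.write(f"# masked_bins: {','.join(map(str, masked))}\n")
        iu, ju = np.nonzero(np.triu(cmap.values))
        vals = cmap.values[iu, ju]
        for i, j, v in zip(iu, ju, vals):
            fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_sparse(path: str, genome: Optional[Genome] = None) -> ContactMap:
    """Read the sparse dialect; a coordinate-only Genome is rebuilt from the
    header unless one is supplied."""
    header = {}
    body = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    header[key.strip()] = val.strip()
                continue
            if line:
                i, j, v = line.split("\t")
                body.append((int(i), int(j), float(v)))
    length = int(header["length"])
    bin_size = int(header["bin_size"])
    if genome is None:
        genome = Genome(name=header.get("genome", "genome"), length=length,
                        circular=bool(int(header.get("circular", "1"))))
    n = n_bins_for(length, bin_size)
    values = np.zeros((n, n))
    for i, j, v in body:
        values[i, j] = v
        values[j, i] = v
    mask = np.zeros(n, dtype=bool)
    masked = header.get("masked_bins", "")
    if masked:
        mask[[int(b) for b in masked.split(",")]] = True
    return ContactMap(genome, bin_size, values, mask, header.get("state", "raw"))
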
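"""Genome coordinates, restriction digestion and fragment attribution.

Coordinates are 0-based and half-open throughout the library; 1-based
numbers appear only in CLI reports.  A genome is a single replicon,
circular by default (the bacterial case), carrying named anchor positions
(``dif``, ``oriC``) and named spans (``terminus``, macrodomains).  A span
may wrap the origin only on a circular genome.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: E. coli K-12 MG1655 (NC_000913) replicon length in bp.
ECOLI_LENGTH = 4_641_652
#: dif site position (bp, 0-based) in NC_000913 coordinates.
ECOLI_DIF = 1_588_800
#: oriC position (bp, 0-based).
ECOLI_ORIC = 3_925_860
#: Terminus region with depleted mid-range contacts under Topo IV loss.
ECOLI_TERMINUS = (1_315_000, 1_830_000)


@dataclass
class Genome:
    """A single circular or linear replicon.

    Parameters
    ----------
    name : str
        Sequence/record name.
    length : int
        Replicon length in bp, > 0.
    circular : bool
        Whether coordinates wrap at ``length``.
    sequence : str, optional
        Nucleotide sequence; required only for digestion.
    anchors : dict
        Named point coordinates in bp (e.g. ``dif``, ``oriC``), each in
        ``[0, length)``.
    spans : dict
        Named half-open ``(start, end)`` intervals in bp.  ``end < start``
        denotes an origin-wrapping span (circular genomes only).
    """

    name: str
    length: int
    circular: bool = True
    sequence: Optional[str] = None
    anchors: dict = field(default_factory=dict)
    spans: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        for key, pos in self.anchors.items():
            if not 0 <= pos < self.length:
                raise ValueError(f"anchor {key!r} at {pos} outside [0, {self.length})")
        for key, (start, end) in self.spans.items():
            if not (0 <= start < self.length and 0 <= end <= self.length):
                raise ValueError(f"span {key!r} = {(start, end)} outside genome")
            if end < start and not self.circular:
                raise ValueError(f"span {key!r} wraps the origin of a linear genome")

    def span_contains(self, span_name: str, pos: int) -> bool:
        """Membership of ``pos`` in a named (possibly wrapping) span."""
        start, end = self.spans[span_name]
        if end >= start:
            return start <= pos < end
        return pos >= start or pos < end


def ecoli_mg1655(sequence: Optional[str] = None) -> Genome:
    """The NC_000913 coordinate frame with the standard anchors.

    Only coordinates are bundled; pass ``sequence`` for digestion.
    """
    return Genome(
        name="NC_000913",
        length=ECOLI_LENGTH if sequence is None else len(sequence),
        circular=True,
        sequence=sequence,
        anchors={"dif": ECOLI_DIF, "oriC": ECOLI_ORIC},
        spans={"terminus": ECOLI_TERMINUS},
    )


def read_fasta(path, record_name: Optional[str] = None, circular: bool = True) -> Genome:
    """Load a genome from a FASTA file.

    The first record is used unless ``record_name`` is given.
    """
    from Bio import SeqIO

    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        if record_name is None or rec.id == record_name:
            seq = str(rec.seq).upper()
            return Genome(name=rec.id, length=len(seq), circular=circular, sequence=seq)
    raise ValueError(f"record {record_name!r} not found in {path}")


@dataclass
class FragmentMap:
    """Restriction fragments tiling a genome.

    ``cut_positions`` are sorted bp offsets.  Fragments are half-open
    ``[start, end)`` intervals; on a circular genome with at least one cut
    the last fragment wraps from the final cut back to the first.  With no
    cuts there is exactly one fragment covering the whole genome.
    """

    genome: Genome
    cut_positions: np.ndarray
    enzyme_site: str = "CCGG"
    cut_offset: int = 1

    def __post_init__(self):
        self.cut_positions = np.asarray(sorted(set(int(c) for c in self.cut_positions)))

    @property
    def n_fragments(self) -> int:
        n = len(self.cut_positions)
        if n == 0:
            return 1
        if self.genome.circular:
            return n
        # linear: [0, c0), [c0, c1), ..., [c_last, L); leading piece absent if c0 == 0
        n_frag = n + 1
        if self.cut_positions[0] == 0:
            n_frag -= 1
        if self.cut_positions[-1] == self.genome.length:
            n_frag -= 1
        return n_frag

    @property
    def fragments(self) -> list:
        """Half-open ``(start, end)`` intervals; a wrapping fragment has end < start."""
        cuts = self.cut_positions
        L = self.genome.length
        if len(cuts) == 0:
            return [(0, L)]
        if self.genome.circular:
            out = [(int(cuts[k]), int(cuts[k + 1])) for k in range(len(cuts) - 1)]
            out.append((int(cuts[-1]), int(cuts[0])))  # wraps the origin
            return out
        bounds = [0] + [int(c) for c in cuts] + [L]
        return [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    def fragment_lengths(self) -> np.ndarray:
        L = self.genome.length
        return np.array([(e - s) if e > s else (L - s + e) for s, e in self.fragments],
                        dtype=int)


def digest(genome: Genome, enzyme_site: str = "CCGG", cut_offset: int = 1) -> FragmentMap:
    """Digest a genome sequence with a fixed-length recognition pattern.

    Sites are located on the forward strand only (palindromic recognition
    sequences need no reverse scan).  On a circular genome, occurrences
    spanning the origin are found as well.  Characters outside ACGT never
    match (counted and logged).  Cut position = site start + ``cut_offset``,
    taken modulo the genome length.
    """
    if genome.sequence is None:
        raise ValueError("sequence required")
    site = enzyme_site.upper()
    if not site or not 0 <= cut_offset <= len(site):
        raise ValueError(f"invalid enzyme site {enzyme_site!r} / cut offset {cut_offset}")
    seq = genome.sequence.upper()
    n_ambiguous = sum(1 for c in set(seq) if c not in "ACGT")
    if n_ambiguous:
        logger.warning(
            "sequence contains %d non-ACGT character type(s); they never match the site",
            sum(seq.count(c) for c in set(seq) if c not in "ACGT"),
        )
    scan = seq + (seq[: len(site) - 1] if genome.circular and len(site) > 1 else "")
    starts = [m.start() for m in re.finditer(f"(?=({re.escape(site)}))", scan)]
    cuts = sorted({(s + cut_offset) % genome.length for s in starts})
    return FragmentMap(genome=genome, cut_positions=np.array(cuts, dtype=int),
                       enzyme_site=site, cut_offset=cut_offset)


def assign_fragment(fragmap: FragmentMap, pos: int) -> int:
    """Index of the fragment whose half-open interval contains ``pos``.

    Wrap-aware bisection over the sorted cut positions; the fragment order
    matches :attr:`FragmentMap.fragments`.
    """
    L = fragmap.genome.length
    if not 0 <= pos < L:
        raise ValueError(f"position {pos} outside [0, {L})")
    cuts = fragmap.cut_positions
    if len(cuts) == 0:
        return 0
    idx = bisect_right(cuts, pos) - 1
    if fragmap.genome.circular:
        return idx if idx >= 0 else len(cuts) - 1  # before the first cut -> wrapping fragment
    # linear: fragments are delimited by [0] + cuts + [L]
    lead = 1 if cuts[0] > 0 else 0
    return idx + lead
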
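"""Reading, writing and filtering of aligned read-pair records.

The text dialect is a minimal `.pairs`-style table: header lines start
with ``#``; body columns are

    readID  chrom1  pos1  chrom2  pos2  strand1  strand2  [mapq1  mapq2]

Positions are 0-based bp.  Records missing the MAPQ columns are treated
as passing the quality filter (with a warning), since nothing can be
concluded about them.  Malformed lines are skipped and counted, never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, TextIO, Union

logger = logging.getLogger(__name__)


class PairRecord(NamedTuple):
    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str = "+"
    strand2: str = "+"
    mapq1: Optional[int] = None  # None = unknown, treated as passing
    mapq2: Optional[int] = None


@dataclass
class PairStats:
    """Bookkeeping for parsing/filtering; filled as the stream is consumed."""

    n_input: int = 0
    n_retained: int = 0
    n_discarded_mapq: int = 0
    n_discarded_chrom: int = 0
    n_malformed: int = 0
    n_missing_mapq: int = 0
    n_same_fragment: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_retained

    @property
    def retained_fraction(self) -> float:
        if self.n_input == 0:
            return float("nan")
        return self.n_retained / self.n_input


def parse_pairs(source: Union[str, TextIO, Iterable[str]],
                stats: Optional[PairStats] = None) -> Iterator[PairRecord]:
    """Yield :class:`PairRecord` from a path, file object, or iterable of lines."""
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    if stats is None:
        stats = PairStats()
    warned_mapq = False
    try:
        for line in source:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if len(fields) >= 9:
                    rec = PairRecord(fields[0], fields[1], int(fields[2]), fields[3],
                                     int(fields[4]), fields[5], fields[6],
                                     int(fields[7]), int(fields[8]))
                elif len(fields) == 7:
                    rec = PairRecord(fields[0], fields[1], int(fields[2]), fields[3],
                                     int(fields[4]), fields[5], fields[6], None, None)
                    stats.n_missing_mapq += 1
                    if not warned_mapq:
                        logger.warning("pairs record without MAPQ columns: treated as passing")
                        warned_mapq = True
                else:
                    raise ValueError("wrong column count")
                if rec.pos1 < 0 or rec.pos2 < 0:
                    raise ValueError("negative position")
            except (ValueError, IndexError):
                stats.n_malformed += 1
                logger.debug("malformed pairs line skipped: %r", line)
                continue
            yield rec
    finally:
        if close:
            source.close()


def write_pairs(records: Iterable[PairRecord], path: str, genome_name: str = "",
                genome_length: Optional[int] = None) -> int:
    """Write records in the text dialect; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("# columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2 mapq1 mapq2\n")
        if genome_name:
            fh.write(f"# chromsize: {genome_name} {genome_length}\n")
        for r in records:
            q1 = "" if r.mapq1 is None else r.mapq1
            q2 = "" if r.mapq2 is None else r.mapq2
            tail = f"\t{q1}\t{q2}" if r.mapq1 is not None else ""
            fh.write(f"{r.read_id}\t{r.chrom1}\t{r.pos1}\t{r.chrom2}\t{r.pos2}"
                     f"\t{r.strand1}\t{r.strand2}{tail}\n")
            n += 1
    return n


def filter_pairs(records: Iterable[PairRecord], mapq_min: int = 31,
                 known_chroms: Optional[set] = None,
                 stats: Optional[PairStats] = None):
    """Quality filter for read pairs.

    A pair is retained iff both mates map to a known chromosome (when
    ``known_chroms`` is given) and both MAPQ values are >= ``mapq_min``.
    The default ``mapq_min=31`` keeps mapping quality strictly above 30.
    Unknown (absent) MAPQ is treated as passing.

    Returns ``(iterator, stats)``; the stats fill in as the iterator is
    consumed (the retained fraction is the "informative reads" proxy).
    """
    if stats is None:
        stats = PairStats()

    def _gen():
        for rec in records:
            stats.n_input += 1
            if known_chroms is not None and (
                    rec.chrom1 not in known_chroms or rec.chrom2 not in known_chroms):
                stats.n_discarded_chrom += 1
                continue
            q1 = rec.mapq1 if rec.mapq1 is not None else mapq_min
            q2 = rec.mapq2 if rec.mapq2 is not None else mapq_min
            if q1 < mapq_min or q2 < mapq_min:
                stats.n_discarded_mapq += 1
                continue
            stats.n_retained += 1
            yield rec

    return _gen(), stats
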
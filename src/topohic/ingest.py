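"""From filtered read pairs to a raw binned contact matrix.

Each retained pair increments the cell ``(bin(pos1), bin(pos2))`` and its
mirror once; a pair with both ends in the same bin increments the diagonal
cell by one.  When a fragment map is supplied, pairs whose two ends fall in
the same restriction fragment are discarded (a proxy for religation and
self-circle events) and counted in the stats.
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np

from .contact_map import ContactMap, n_bins_for
from .genome import FragmentMap, Genome, assign_fragment
from .pairs import PairRecord, PairStats, filter_pairs, parse_pairs


def build_matrix(pairs: Iterable[PairRecord], genome: Genome, bin_size: int,
                 fragmap: Optional[FragmentMap] = None,
                 drop_same_fragment: bool = True,
                 stats: Optional[PairStats] = None) -> Tuple[ContactMap, PairStats]:
    """Bin a stream of (already filtered) pairs into a raw contact matrix."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if stats is None:
        stats = PairStats()
    n = n_bins_for(genome.length, bin_size)
    values = np.zeros((n, n))
    use_frag = fragmap is not None and drop_same_fragment
    for k, rec in enumerate(pairs):
        if not (0 <= rec.pos1 < genome.length and 0 <= rec.pos2 < genome.length):
            raise ValueError(f"pair record {k} has a position beyond the genome "
                             f"({rec.pos1}, {rec.pos2})")
        if use_frag and assign_fragment(fragmap, rec.pos1) == assign_fragment(fragmap, rec.pos2):
            stats.n_same_fragment += 1
            continue
        b1, b2 = rec.pos1 // bin_size, rec.pos2 // bin_size
        if b1 == b2:
            values[b1, b1] += 1.0
        else:
            values[b1, b2] += 1.0
            values[b2, b1] += 1.0
    cmap = ContactMap(genome, bin_size, values, state="raw")
    return cmap, stats


def ingest_pairs_file(path: str, genome: Genome, bin_size: int,
                      mapq_min: int = 31, fragmap: Optional[FragmentMap] = None,
                      drop_same_fragment: bool = True) -> Tuple[ContactMap, PairStats]:
    """Parse, MAPQ-filter and bin a pairs file in one pass (shared stats)."""
    stats = PairStats()
    records = parse_pairs(path, stats=stats)
    retained, stats = filter_pairs(records, mapq_min=mapq_min,
                                   known_chroms={genome.name}, stats=stats)
    return build_matrix(retained, genome, bin_size, fragmap=fragmap,
                        drop_same_fragment=drop_same_fragment, stats=stats)
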
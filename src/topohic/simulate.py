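"""Synthetic contact maps, read pairs and foci tables on a circular genome.

The generator plants parameterized versions of the chromosome-reorganization
signatures that Topo IV inactivation produces in *E. coli* Hi-C maps, so
every comparison operation in :mod:`topohic.compare` can be exercised and
calibrated without sequencing data:

* a power-law contact decay ``P(s) = (s0 + s) ** -gamma`` on the circle;
* a short-to-mid-range contact boost along the arms (50-300 kb by default),
  the cis rendering of precatenane-mediated inter-sister contacts;
* a terminus region (1315-1830 kb) with depleted mid-range contacts, a
  boost of very short-range (<50 kb) contacts, and a sharp contact border
  at *dif*;
* additive, distance-independent "butterfly wing" stripes joining the two
  ~100 kb *dif* flanks to the opposing chromosome arms, with the *dif* bin
  itself excluded.

The wing amplitude ``alpha`` is defined as the fold enrichment of total
contact mass over the wing cells beyond the quantifier's near-diagonal
guard: the additive level is ``(alpha - 1)`` times the mean background over
those cells, which makes the planted fold directly recoverable.

All sampling is driven by a single integer seed via
``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .contact_map import ContactMap, n_bins_for
from .genome import ECOLI_DIF, ECOLI_LENGTH, ECOLI_ORIC, ECOLI_TERMINUS, FragmentMap, Genome
from .pairs import PairRecord

Span = Tuple[int, int]


@dataclass
class DecayParams:
    """Power-law distance decay P(s) = (s0 + s) ** -gamma (s in bp)."""
    gamma: float = 0.8
    s0: float = 10_000.0


@dataclass
class PrecatenaneParams:
    """Multiplicative short/mid-range boost outside the terminus (mutant only)."""
    beta: float = 0.4            # amplitude: contacts scaled by (1 + beta) in band
    d_lo: int = 50_000
    d_hi: int = 300_000


@dataclass
class TerminusParams:
    """Terminus-internal reorganization (mutant only)."""
    span: Span = ECOLI_TERMINUS
    depletion: float = 0.5       # iota in (0, 1]: mid-range terminus cells scaled down
    dif_border: float = 0.5      # extra factor for cells straddling dif
    short_boost: float = 0.5     # <short_range cells scaled by (1 + short_boost)
    short_range: int = 50_000


@dataclass
class WingParams:
    """Additive, distance-independent butterfly-wing stripes (mutant only)."""
    alpha: float = 1.5           # fold enrichment of wing-cell contact mass
    anchor_width: int = 100_000  # per dif flank (the two flanks = the dif zone)
    guard: int = 300_000         # separation beyond which alpha is defined


@dataclass
class SimParams:
    genome_length: int = ECOLI_LENGTH
    bin_size: int = 5_000
    dif: int = ECOLI_DIF
    oriC: int = ECOLI_ORIC
    decay: DecayParams = field(default_factory=DecayParams)
    precatenane: PrecatenaneParams = field(default_factory=PrecatenaneParams)
    terminus: TerminusParams = field(default_factory=TerminusParams)
    wings: Optional[WingParams] = field(default_factory=WingParams)
    total_pairs: int = 1_000_000
    seed: int = 0

    def make_genome(self) -> Genome:
        return Genome(name="sim", length=self.genome_length, circular=True,
                      anchors={"dif": self.dif, "oriC": self.oriC},
                      spans={"terminus": self.terminus.span})

    def __post_init__(self):
        t0, t1 = self.terminus.span
        if not (0 <= t0 < self.genome_length and 0 < t1 <= self.genome_length):
            raise ValueError("terminus span outside genome")
        if self.precatenane.d_lo >= self.precatenane.d_hi:
            raise ValueError("precatenane range needs d_lo < d_hi")
        if self.wings is not None and self.wings.alpha < 1:
            raise ValueError("wing alpha must be >= 1")
        if not 0 < self.terminus.depletion <= 1:
            raise ValueError("terminus depletion must be in (0, 1]")


def scaled_params(genome_length: int = ECOLI_LENGTH, bin_size: int = 5_000,
                  **kwargs) -> SimParams:
    """SimParams with the E. coli feature geometry rescaled to a different
    genome length (useful for quick, small simulations)."""
    f = genome_length / ECOLI_LENGTH
    defaults = dict(
        genome_length=genome_length, bin_size=bin_size,
        dif=int(ECOLI_DIF * f), oriC=int(ECOLI_ORIC * f),
        terminus=TerminusParams(span=(int(ECOLI_TERMINUS[0] * f),
                                      int(ECOLI_TERMINUS[1] * f))),
        precatenane=PrecatenaneParams(d_lo=max(2 * bin_size, int(50_000 * f)),
                                      d_hi=max(4 * bin_size, int(300_000 * f))),
        wings=WingParams(anchor_width=max(bin_size, int(100_000 * f)),
                         guard=max(2 * bin_size, int(300_000 * f))),
    )
    defaults.update(kwargs)
    return SimParams(**defaults)


def expected_map(params: SimParams, condition: str = "wt") -> ContactMap:
    """Noise-free expected-intensity matrix for one condition.

    ``lambda(i, j) = P(s) * boost * insulation + wing`` with the mutant-only
    features switched off under ``condition='wt'``.  The matrix is scaled
    to unit mean and symmetric; its state is ``"expected"``.
    """
    if condition not in ("wt", "mutant"):
        raise ValueError("condition must be 'wt' or 'mutant'")
    genome = params.make_genome()
    bs = params.bin_size
    n = n_bins_for(params.genome_length, bs)
    idx = np.arange(n)
    k = np.abs(idx[:, None] - idx[None, :])
    k = np.minimum(k, n - k)
    s = k * float(bs)                                   # bp separation
    lam = (params.decay.s0 + s) ** (-params.decay.gamma)

    mids = (idx * bs + np.minimum((idx + 1) * bs, params.genome_length)) / 2.0
    t0, t1 = params.terminus.span
    in_ter = (mids >= t0) & (mids < t1) if t1 >= t0 else (mids >= t0) | (mids < t1)

    if condition == "mutant":
        pc = params.precatenane
        if pc.beta > 0:
            band = (s >= pc.d_lo) & (s <= pc.d_hi)
            out_ter = ~in_ter
            both_out = out_ter[:, None] & out_ter[None, :]
            lam = np.where(band & both_out, lam * (1.0 + pc.beta), lam)

        ter = params.terminus
        both_in = in_ter[:, None] & in_ter[None, :]
        short = s < ter.short_range
        lam = np.where(both_in & short, lam * (1.0 + ter.short_boost), lam)
        lam = np.where(both_in & ~short, lam * ter.depletion, lam)
        # sharp border at dif: terminus-internal cells straddling dif
        left_of_dif = mids < params.dif
        straddle = left_of_dif[:, None] != left_of_dif[None, :]
        lam = np.where(both_in & straddle & ~short, lam * ter.dif_border, lam)

        if params.wings is not None:
            wi, wj = _wing_cell_indices(params, n)
            sep = np.minimum(np.abs(wi - wj), n - np.abs(wi - wj)) * bs
            ref = sep > params.wings.guard
            if ref.any():
                w_level = (params.wings.alpha - 1.0) * float(lam[wi[ref], wj[ref]].mean())
                lam[wi, wj] += w_level
                lam[wj, wi] += w_level

    lam /= lam.mean()
    cmap = ContactMap(genome, bs, lam, state="expected")
    cmap.meta["condition"] = condition
    return cmap


def _wing_cell_indices(params: SimParams, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Upper-wing cell set: (left flank of dif x left arm) U (right flank x
    right arm); arms run from the terminus edges to oriC; dif bin excluded."""
    bs = params.bin_size
    dif_bin = params.dif // bs
    w_bins = max(1, params.wings.anchor_width // bs)
    t0, t1 = params.terminus.span
    anchor_left = np.arange(dif_bin - w_bins, dif_bin) % n
    anchor_right = np.arange(dif_bin + 1, dif_bin + 1 + w_bins) % n

    def span_bins(start, end):
        b0, b1 = start // bs, -(-end // bs)
        if end >= start:
            return np.arange(b0, min(b1, n))
        return np.concatenate([np.arange(b0, n), np.arange(0, b1)])

    arm_left = span_bins(params.oriC, t0)   # wraps through the origin
    arm_right = span_bins(t1, params.oriC)
    ii, jj = [], []
    for anc, arm in ((anchor_left, arm_left), (anchor_right, arm_right)):
        ai, aj = np.meshgrid(anc, arm, indexing="ij")
        ii.append(ai.ravel())
        jj.append(aj.ravel())
    return np.concatenate(ii), np.concatenate(jj)


def sample_counts(expected: ContactMap, total_pairs: int, seed: int) -> ContactMap:
    """Poisson-sample a raw count matrix from expected intensities.

    Upper-triangle cells (diagonal included) are independent Poisson with
    means proportional to the expected map and summing to ``total_pairs``
    in expectation; the result is mirrored to symmetry.
    """
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    if np.any(expected.values < 0):
        raise ValueError("expected intensities must be >= 0")
    rng = np.random.default_rng(seed)
    n = expected.n_bins
    iu, ju = np.triu_indices(n)
    lam = expected.values[iu, ju]
    lam = lam / lam.sum() * float(total_pairs)
    counts = rng.poisson(lam).astype(float)
    values = np.zeros((n, n))
    values[iu, ju] = counts
    values[ju, iu] = counts
    out = ContactMap(expected.genome, expected.bin_size, values,
                     expected.mask.copy(), state="raw")
    out.meta["condition"] = expected.meta.get("condition")
    return out


def sample_pairs(expected: ContactMap, genome: Optional[Genome] = None,
                 fragmap: Optional[FragmentMap] = None,
                 total_pairs: int = 1_000_000, seed: int = 0,
                 mapq_noise: float = 0.0) -> Iterator[PairRecord]:
    """Draw a `.pairs` record stream from an expected contact matrix.

    Bin pairs are drawn multinomially from the normalized expected upper
    triangle; read positions are uniform within their bin, so re-binning
    the stream at the same bin size recovers the drawn count matrix
    exactly.  A ``mapq_noise`` fraction of records gets MAPQ 10 (one mate),
    the rest MAPQ 60.  ``fragmap`` is accepted for signature symmetry with
    the ingest path but unused (positions are bin-uniform).
    """
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    if not 0 <= mapq_noise <= 1:
        raise ValueError("mapq_noise must be a fraction in [0, 1]")
    genome = expected.genome if genome is None else genome
    rng = np.random.default_rng(seed)
    n = expected.n_bins
    bs = expected.bin_size
    iu, ju = np.triu_indices(n)
    p = expected.values[iu, ju]
    p = p / p.sum()
    cell_counts = rng.multinomial(total_pairs, p)
    nz = cell_counts > 0
    b1 = np.repeat(iu[nz], cell_counts[nz])
    b2 = np.repeat(ju[nz], cell_counts[nz])
    order = rng.permutation(total_pairs)
    b1, b2 = b1[order], b2[order]

    def width(b):
        return np.minimum((b + 1) * bs, genome.length) - b * bs

    pos1 = b1 * bs + rng.integers(0, width(b1))
    pos2 = b2 * bs + rng.integers(0, width(b2))
    strands = np.array(["+", "-"])
    s1 = strands[rng.integers(0, 2, total_pairs)]
    s2 = strands[rng.integers(0, 2, total_pairs)]
    noisy = rng.random(total_pairs) < mapq_noise
    mapq1 = np.where(noisy, 10, 60)
    for k in range(total_pairs):
        yield PairRecord(f"r{k}", genome.name, int(pos1[k]), genome.name,
                         int(pos2[k]), str(s1[k]), str(s2[k]),
                         int(mapq1[k]), 60)


# ---------------------------------------------------------------------------
# Foci simulation
# ---------------------------------------------------------------------------

@dataclass
class FociSimParams:
    """Generator settings for per-cell fluorescent-foci tables.

    Defaults emulate the measured two-color regime: ~600 cells per
    condition, 1-2 foci per tag, inter-tag (e.g. ter vs left) distances
    around 0.8 um, and a colocalization (closest distance < 0.25 um)
    probability of 9% in wild type, doubled to 18% when the mutant
    modifiers are applied.
    """

    n_cells: int = 600
    tags: Tuple[str, str] = ("ter", "left")
    cell_length_mean: float = 2.5    # um
    cell_length_sd: float = 0.35
    p_two_foci: float = 0.3          # per tag
    coloc_prob: float = 0.09         # wt probability of a < 0.25 um closest pair
    coloc_excess: float = 0.09       # added to coloc_prob under condition="mutant"
    distance_mean: float = 0.9       # um, non-colocalized pairs (offset applies)
    distance_sd: float = 0.30
    distance_floor: float = 0.30     # non-colocalized distances stay above this
    var_scale: float = 1.0           # multiplies distance_sd under "mutant"
    axial_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_two_foci, self.coloc_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.coloc_prob + self.coloc_excess <= 1:
            raise ValueError("coloc_prob + coloc_excess must be in [0, 1]")


def simulate_foci(params: FociSimParams, condition: str = "wt") -> pd.DataFrame:
    """Synthetic per-cell foci coordinate table.

    Columns: ``cell_id, cell_length_um, tag, x_um, y_um, axial``.  The
    first tag's foci sit near the 1/4 and 3/4 cell positions (two-focus
    cells) or mid-cell (single focus); the second tag's first focus is
    placed at a drawn distance from one first-tag focus — below 0.25 um
    with the planted colocalization probability, otherwise above the
    distance floor.
    """
    if condition not in ("wt", "mutant"):
        raise ValueError("condition must be 'wt' or 'mutant'")
    rng = np.random.default_rng(params.seed)
    p_coloc = params.coloc_prob + (params.coloc_excess if condition == "mutant" else 0.0)
    sd = params.distance_sd * (params.var_scale if condition == "mutant" else 1.0)
    tagA, tagB = params.tags
    rows: List[tuple] = []
    for c in range(params.n_cells):
        length = max(1.0, rng.normal(params.cell_length_mean, params.cell_length_sd))
        # tag A foci at ~1/4 and ~3/4 (or mid-cell when single)
        if rng.random() < params.p_two_foci:
            ax_a = [np.clip(rng.normal(0.25, params.axial_sd), 0, 1),
                    np.clip(rng.normal(0.75, params.axial_sd), 0, 1)]
        else:
            ax_a = [np.clip(rng.normal(0.5, params.axial_sd), 0, 1)]
        a_xy = [(a * length, rng.normal(0.0, 0.1)) for a in ax_a]
        for (x, y), a in zip(a_xy, ax_a):
            rows.append((f"cell{c}", length, tagA, x, y, a))
        # tag B: first focus tied to a random A focus
        ref_x, ref_y = a_xy[rng.integers(0, len(a_xy))]
        if rng.random() < p_coloc:
            d = rng.uniform(0.0, 0.2)
        else:
            d = params.distance_floor + abs(rng.normal(params.distance_mean
                                                       - params.distance_floor, sd))
        theta = rng.uniform(0, 2 * np.pi)
        bx = np.clip(ref_x + d * np.cos(theta), 0, length)
        by = ref_y + d * np.sin(theta)
        # clipping along the cell axis must not break the planted distance
        if np.hypot(bx - ref_x, by - ref_y) < d - 1e-9:
            bx = ref_x + d * np.cos(theta)
        rows.append((f"cell{c}", length, tagB, float(bx), float(by), float(np.clip(bx / length, 0, 1))))
        if rng.random() < params.p_two_foci:
            # second B focus near the opposite quarter, kept at least the
            # distance floor away from every A focus so it cannot create
            # an unplanted colocalization event
            center = 0.75 if bx / length < 0.5 else 0.25
            for _ in range(100):
                ax_b = np.clip(rng.normal(center, params.axial_sd), 0, 1)
                x2, y2 = ax_b * length, rng.normal(0.0, 0.1)
                if all(np.hypot(x2 - x, y2 - y) >= params.distance_floor
                       for x, y in a_xy):
                    break
            else:
                y2 = params.distance_floor + 0.2
            rows.append((f"cell{c}", length, tagB, float(x2), float(y2), float(ax_b)))
    return pd.DataFrame(rows, columns=["cell_id", "cell_length_um", "tag",
                                       "x_um", "y_um", "axial"])
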
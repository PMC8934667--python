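# Methods

This note documents the models, conventions and numerical choices behind
`topohic`, and what the synthetic-data generator does and does not emulate.

## Coordinates and containers

All library coordinates are 0-based, half-open; 1-based numbers appear only
at CLI boundaries. A genome is a single replicon (circular by default) with
named anchor points (*dif*, *oriC*) and spans (terminus, macrodomains); a
span may wrap the origin only on a circular genome. Contact matrices are
dense symmetric float64 arrays — a bacterial genome at 2–10 kb bins is well
under a thousand bins, so sparse storage would only add indirection. The
genomic separation between bins i and j is circular:
`s(i,j) = min(|i−j|, N−|i−j|) · bin_size`. The last genomic bin may be
shorter than the bin size and is kept, giving `ceil(L / bin_size)` bins.

The on-disk matrix dialect is plain text (`#` header lines, then
upper-triangle `i<TAB>j<TAB>value` rows) with values written via `repr`,
so a write/read round trip is bit-exact.

## Ingest

Digestion scans the forward strand for a fixed recognition pattern
(HpaII `CCGG` with cut offset 1 by default; palindromic sites need no
reverse scan), including occurrences spanning the origin of a circular
genome. Characters outside ACGT never match and are logged. Fragments are
the half-open intervals between consecutive cuts; on a circular genome the
last fragment wraps, and with no sites the whole genome is one fragment.
Fragment attribution is bisection over the sorted cut positions, validated
against a linear interval scan in the tests.

Read pairs are filtered by requiring both mates on a known chromosome and
both MAPQ values at least 31 — the inclusive encoding of "strictly greater
than 30". Records without MAPQ columns are treated as passing (with a
warning); malformed lines are skipped and counted, never silently dropped.
The retained fraction is reported as the informative-read proxy. Binning
increments `(bin(pos1), bin(pos2))` and its mirror once per pair, with
diagonal pairs counted once. When a fragment map is supplied, pairs with
both ends in one fragment are removed by default as a minimal religation /
self-circle proxy — the exact uninformative-pair filters of upstream
pipelines vary, so this choice is explicit and its effect is always
reported in the stats. Strand fields are parsed and preserved but play no
role in binning.

## Masking and SCN normalization

Before balancing, bins whose marginal falls below a fraction (default 0.1)
of the median nonzero marginal are masked and zeroed. The rule is a package
policy: upstream pipelines mask poorly covered bins but publish no single
threshold, so the policy is explicit, logged, and recorded in the output
metadata.

Sequential component normalization alternates row and column division by
the component norm (L1 by default; L2 available) until the maximum
deviation of unmasked row norms from 1 falls below `tol` (default 1e-6,
at most 200 iterations), then symmetrizes with `(M + Mᵀ)/2` — alternating
balancing necessarily ends half a step asymmetric. After L1-SCN every
unmasked row sums to 1 within `2·tol`, so a matrix row reads directly as a
contact-frequency distribution; this is what makes a single-bin virtual-4C
profile sum to ~1. The convergence metric is the row-sum deviation itself
(a directly testable invariant) rather than the change in the matrix. SCN
is scale-invariant, permutation-equivariant and idempotent; the tests
verify all three plus cellwise agreement with an independent ten-line
reference implementation.

## Comparison operations

**Ratio matrices.** `log2((mutant + p)/(control + p))` cellwise, on maps
of identical genome, bin size and normalization state. The pseudocount
defaults to the smallest positive value across both maps and is always
recorded; with that symmetric default the operation is antisymmetric under
operand swap. Masked cells carry NaN, never 0 — on a log-ratio scale zero
means "no change", which a masked cell must not assert.

**Scalograms (distance-stratified ratio plots).** For each bin b and
separation d (default grid 5 kb to 1 Mb in 5 kb steps, strictly below half
the circular genome length), the average contact `AC(b,d)` is the mean of
the two map values exactly d upstream and downstream (one mean of two
values — orientation is not distinguished), and the scalogram cell is
`log2((AC_mut + p)/(AC_ctl + p))`.

**Decay ratio curves.** `log2(P_mut(s)/P_ctl(s))` where `P(s)` is the
genome-wide mean contact at separation s. Summing over bins before taking
the log makes this curve robust to shot noise at realistic sequencing
depth, where the mean of cellwise log ratios is dominated by the log of
small Poisson counts. It equals the scalogram column means whenever the
difference between conditions is purely distance-multiplicative (a tested
consistency property). Because balanced maps are compositional (rows sum
to 1), a genuine gain at some separations forces a uniform offset
elsewhere; the `center=True` option subtracts the across-separation median
to remove that offset, and the row-centered scalogram
(`Scalogram.row_centered()`) does the same per bin.

**Virtual 4C.** The anchor bin's matrix row, or the mean of rows over an
anchor span, masked bins NaN.

**Windowed Z-transformation.** For disjoint query and target spans,
`c_j = Σ_{i∈query} M[i,j]` over target bins j, returned as
`(c_j − mean(c))/sd(c)` with the population standard deviation over the
unmasked target bins (the output therefore has mean 0 and sd 1 by
construction; a constant `c` is an error, not a zero track). The
population rather than sample sd is a documented choice; at the hundreds
of target bins involved the difference is negligible.

**Butterfly-wing enrichment.** The default geometry places one anchor per
wing in each 100-kb flank of *dif* (together, the ~200-kb *dif* zone) and
runs each arm from the terminus edge on that side to *oriC*; a
near-diagonal guard (default 300 kb) keeps short-range structure out. The
*dif* bin is excluded from the statistics but still evaluated in the
per-anchor-bin profile so its characteristic dip stays visible. The
headline fold is the contact mass of the wing cells relative to the *same
anchor rows'* cells on the opposing arm at the same guard: referencing the
rows' own background cancels the per-row rescaling that iterative
balancing applies to bins carrying extra stripe mass (balancing otherwise
attenuates a planted 2-fold stripe to ~1.6-fold). When the ratio map still
references its source maps the fold uses ratios of summed linear contacts,
which is unbiased at low per-cell counts; the mean cellwise log2 ratio is
reported alongside.

**Distance-law test.** Ordinary least squares of `log(value)` on
`log(separation)` over a cell set, by default after averaging cells within
each separation class — fitting individual noisy cells in log space
censors the nonpositive ones and biases the slope. Preconditions: at least
10 usable cells spanning a ≥ 4-fold separation range. For the wing
diagnostic (`wing_distance_law`), the control map is first rescaled to the
mutant per separation class using only the anchor rows' unperturbed
background columns (the opposing arm, excluding the terminus region, whose
internal contacts are themselves reorganized); the excess on the wing
cells is then fitted. A genuine distance-independent hub gives a slope
near 0 while the background decays at ≈ −γ. The control map is always
available in a differential design, so this subtraction is the operative
procedure on real data too.

## The synthetic-data generator

The expected intensity is
`λ(i,j) = P(s)·boost(i,j)·insul(i,j) + wing(i,j)`, scaled to unit mean,
with `P(s) = (s0 + s)^(−γ)`. Defaults: γ = 0.8, s0 = 10 kb — a
qualitatively bacterial decay; these are knobs, not biological estimates.
The planted features, all off under the wild-type condition:

* **Precatenane boost** — cells with both bins outside the terminus and
  separation in [50, 300] kb are multiplied by `1 + β` (default β = 0.4,
  chosen once as a clearly detectable but sub-2-fold change).
* **Terminus reorganization** — within the 1315–1830 kb span,
  above-50 kb cells are multiplied by ι (default 0.5), cells straddling
  *dif* by an additional border factor (default 0.5), and sub-50 kb cells
  by `1 + 0.5`.
* **Butterfly wings** — an additive, distance-independent level on
  (dif-flank × opposing-arm) cells, *dif* bin excluded. The amplitude α is
  defined as the fold enrichment of total contact mass over the wing cells
  beyond the quantifier's guard: the additive level is `(α−1)` times the
  mean background over those cells, which makes a planted α directly
  recoverable and makes the wing cells distance-independent by
  construction. Default α = 1.5. Wings are additive rather than
  multiplicative precisely so that they represent a 3-D contact hub that
  does not follow the distance law.

The generator renders everything in cis on a single replicon. That is
deliberate: conventional Hi-C cannot distinguish sister chromatids, so
inter-sister (precatenane) contacts appear inside the same matrix, exactly
as observed experimentally. The generator does not model polymer dynamics,
replication progression, or a second replicon, and its amplitudes for the
terminus features are chosen only to be detectable — passing recovery
tests demonstrates that the analysis chain is faithful, not that the
biology has these magnitudes.

Count sampling draws independent Poisson cells on the upper triangle with
means proportional to λ and summing to the requested depth in expectation,
then mirrors. Pairs sampling draws bin pairs multinomially, places read
positions uniformly within bins (so re-binning recovers the drawn counts
exactly), and assigns MAPQ 60 except for a configurable fraction given
MAPQ 10 on one mate — with a noise fraction of 0.2 and the default filter,
retention is 80% by construction. All sampling is reproducible from a
single integer seed.

The foci generator emits per-cell tables (cell length ~ N(2.5, 0.35) µm,
1–2 foci per tag) in which the inter-tag distance is drawn below 0.25 µm
with the planted colocalization probability (defaults: 9% wild type, 18%
mutant) and otherwise from a floored folded normal (0.3 + |N(0.6, 0.3)| µm,
sd scalable per condition). Second foci are kept at least the floor away
from the partner tag's foci so they cannot create unplanted colocalization
events. The tables emulate coordinate output of a spot-detection pipeline;
they do not model point-spread overlap, z-projection artifacts or
segmentation errors, so recovery tests validate the statistics, not the
imaging.

## Foci statistics

Distances are 2-D Euclidean in image coordinates (µm), matching
epifluorescence projections; no z. Per cell, all tagA × tagB focus pairs
are enumerated; closest is the minimum and furthest the maximum (equal
with one focus each). Cells missing a tag are skipped and counted; cells
with more than two foci for a tag are excluded with a warning.
Colocalization is the fraction of cells with closest distance below
0.25 µm, with a Wilson binomial confidence interval. The variance F test
puts the larger unbiased variance on top and doubles the smaller tail
(capped at 1), making it symmetric in its arguments; its type-I error is
calibrated in the tests (0.05 ± 0.01 at 10⁴ null replicates). Both pooled
and per-replicate testing are provided, since either convention is
defensible. Relative positions fold about mid-cell (`x → min(x, 1−x)`) or
orient each cell so its first focus lies in the first half, then histogram.

## Problem sizes

The test suite and the acceptance script run the full-size genome
(4,641,652 bp at 5-kb bins, 929 bins) at one million read pairs per
condition — enough for every planted feature to be recovered through the
sampled, normalized path — with feature-recovery sub-checks using
single-feature simulations so the compositional effects of one feature do
not contaminate the read-out of another. Foci analyses use 600 cells per
condition and the F-test calibration 10⁴ replicates of n = 200. The whole
suite completes in well under a minute of compute.

## Known limitations

* Single replicon only; no multi-chromosome genomes, no trans contacts.
* The same-fragment filter is a minimal stand-in for the fuller
  event-classification filters (dangling ends, self-circles) of upstream
  Hi-C pipelines.
* SCN is the only balancing method (no ICE/KR variants); masked-bin policy
  is threshold-based, not model-based.
* The wing quantifier assumes the default geometry (dif flanks vs arms up
  to oriC) unless explicit spans are given; strongly displaced wings
  (e.g. after large inversions) should be measured with explicit spans.
* No domain-boundary (CID) detector is included; the terminus border at
  *dif* is quantified only through the ratio and z-score readouts.
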
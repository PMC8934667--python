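# topohic

Comparative Hi-C analysis of bacterial chromosome reorganization, built for
the study of topoisomerase mutants in *Escherichia coli*.

When Topo IV — the main bacterial decatenase — is inactivated, the
chromosome's contact map reorganizes in three characteristic ways: contacts
in the 50–300 kb range increase along both replichores (the signature of
persistent precatenanes between sister chromatids), mid-range contacts
collapse inside the terminus region (1315–1830 kb, with a sharp border at
*dif* and a compensating gain below 50 kb), and two "butterfly wing"
stripes of distance-independent long-range contacts appear between the
~100-kb flanks of *dif* and the rest of each replichore, sparing the *dif*
bin itself. `topohic` provides the full analysis chain needed to detect and
quantify these signatures in single-replicon Hi-C data, a synthetic-data
generator that plants parameterized versions of each one, and the
interfocal-distance statistics used for the matched fluorescent-tagging
microscopy.

## What it computes

* **Ingest** — restriction digestion (HpaII `C^CGG` by default) of a
  circular or linear genome, fragment attribution by wrap-aware bisection,
  MAPQ filtering of `.pairs`-style read pairs (both mates strictly above
  Q30 by default), and binning into symmetric contact matrices at 2/5/10 kb.
* **Normalize** — coverage-based bin masking and sequential component
  normalization (SCN): alternately divide rows and columns by their sums
  until every unmasked row sums to 1 within tolerance, then symmetrize.
* **Compare** — cellwise log2 ratio matrices `log2((M+p)/(C+p))`;
  distance-stratified ratio plots (scalograms) of the average contact
  `AC(b, d)` each bin makes at increasing separations; genome-wide decay
  ratio curves `log2(P_mut(s)/P_ctl(s))`; virtual-4C profiles (a bin's
  matrix row read as a contact-frequency track); windowed Z-transformation
  `z_j = (c_j − ⟨c⟩)/σ(c)` of the contacts a query window makes with a
  target region; butterfly-wing enrichment (stripe fold over the same
  anchor rows' background) with per-bin profiles; and a log–log
  distance-law slope test that separates genuine 3-D contact hubs
  (slope ≈ 0) from decaying background (slope < 0).
* **Simulate** — expected-intensity maps `λ(i,j) = P(s)·boost·insulation +
  wing` on a circular genome with `P(s) = (s0+s)^(−γ)`, Poisson-sampled
  count matrices, `.pairs` files that re-ingest to the exact sampled
  counts, and per-cell foci coordinate tables with planted colocalization
  probabilities and distance variances.
* **Foci statistics** — per-cell closest/furthest interfocal distances,
  colocalization fractions (< 250 nm) with binomial confidence intervals,
  two-sided variance F tests, and cell-axis relative-position histograms.

## Worked example

Simulate a wild type and a Topo IV-deficient mutant at one million read
pairs, normalize, and quantify the butterfly wings:

```python
import topohic as th

params = th.SimParams()            # 4,641,652-bp genome, 5-kb bins,
                                   # wings planted at 1.5-fold
wt  = th.expected_map(params, "wt")
mut = th.expected_map(params, "mutant")

def pipeline(exp, seed):
    raw = th.sample_counts(exp, total_pairs=1_000_000, seed=seed)
    return th.scn_normalize(th.mask_sparse_bins(raw))

wt_n, mut_n = pipeline(wt, 1), pipeline(mut, 2)
ratio = th.ratio_map(mut_n, wt_n)
wings = th.wing_enrichment(ratio)
print(f"wing fold enrichment: {wings.fold:.3f} over {wings.n_cells} cells")

wing_fit, bg_fit = th.wing_distance_law(mut_n, wt_n)
print(f"wing slope {wing_fit.slope:+.3f}, background {bg_fit.slope:+.3f}")
```

Output:

```
wing fold enrichment: 1.487 over 15760 cells
wing slope -0.014, background -0.818
```

The wing fold recovers the planted 1.5-fold enrichment of the *dif* zone;
the excess contacts are flat in separation (slope ≈ 0, i.e. they do not
follow the genomic distance law) while the background decays with the
expected slope ≈ −γ.

The same analyses are available from the shell:

```bash
topohic sim map wt.mat  --condition wt     --seed 1
topohic sim map mut.mat --condition mutant --seed 2
topohic normalize wt.mat wt.nrm
topohic normalize mut.mat mut.nrm
topohic ratio mut.nrm wt.nrm ratio.png
topohic v4c wt.nrm --anchor 1588801 --out-bedgraph dif_4c.bedgraph
```

## Layout

```
src/topohic/
  genome.py        genomes, digestion, fragment attribution
  pairs.py         .pairs dialect, MAPQ filtering
  contact_map.py   matrix container + sparse text format
  ingest.py        pairs -> raw binned matrix
  normalize.py     bin masking, SCN balancing
  compare.py       ratios, scalograms, 4C, z-scores, wings, distance law
  simulate.py      synthetic maps, pairs, foci tables
  foci.py          interfocal-distance statistics
  plotting.py      heatmaps, tracks, BEDGRAPH export
  cli.py           command-line interface
```

See `docs/methods.md` for the models, conventions and numerical choices.
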
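# Methods

This note documents the models, conventions, parameters and known
limitations behind `phicmap`, in the order data flows through the pipeline.

## Conventions

- All replicons are circular. Circular distance is
  `s = min(|p1−p2|, L−|p1−p2|)`; every module uses this one definition.
- Bins are 0-based half-open `[k·bin, (k+1)·bin)`; the last bin may be
  short. In-memory coordinates are 0-based bp; `.pairs` and alignment TSVs
  are 1-based on disk; BED/bedGraph follow their own specs.
- Every stochastic function takes an explicit integer seed and is
  byte-deterministic given (parameters, seed).

## Contact maps

**Binning.** Each pair increments `M[b1,b2]` and its mirror; intra-bin
pairs increment the diagonal once, so the upper triangle (diagonal
included) sums to the pair count exactly.

**ICE balancing.** Iterative proportional fitting: at each step the
per-bin marginal relative to the unmasked mean is divided out of rows and
columns; iteration stops when the largest relative bias update falls below
`tol` (default 1e-6, `max_iter` 300). Bins with raw marginal below
`min_coverage_fraction` (default 0.1) of the mean marginal are masked
first. The accumulated bias vector is stored so
`raw = balanced × b_i × b_j` holds exactly. At convergence the row-sum
coefficient of variation over unmasked bins is far below 1e-5. The
algorithm is standard; the defaults are this package's choices.

**Downsampling** draws from the multivariate hypergeometric distribution
over upper-triangle pixel counts, so the subsampled total is exact and the
result is a without-replacement subsample of the original contacts.

**Log2-ratio maps** scale the two matrices to equal totals before applying
`log2((a+p)/(b+p))` with pseudocount `p = 1` raw count (a declared default;
no principled value exists). Masked bins propagate as NaN.

**Distance law.** Mean contact per bin-pair at each circular separation,
aggregated into log-spaced strata weighted by pair counts. On generator
output with decay exponent α = 1 the fitted log-log slope recovers −1
within ±0.1 at 10⁶ contacts (fit over 40 kb–900 kb to avoid the
`(1+s) ≈ s` distortion at 1–3 bins).

**SCC.** Both matrices are mean-filtered (half-width `smooth_h`, wrapped),
then per-diagonal Pearson correlations up to `max_dist` are combined with
HiCrep's variance weights `N_d·sd(x_d)·sd(y_d)`. Zero-variance strata are
skipped; strata of identical content contribute r = 1 exactly, so
`scc(m, m) == 1.0` bit-exactly. Diagonals are taken linearly (not
wrapped), as in the original method.

## Genome tracks

**parS scan.** The 16-mer consensus `TGTTTCACGTGAAACA` is scanned at every
circular offset on both strands by vectorized Hamming counting; a locus
matching on both strands (the consensus is palindromic, so exact hits
always do) is reported once with the lower mismatch count. Default
threshold: 2 mismatches.

**GC skew and ori/ter.** Windowed skew `(G−C)/(G+C)` (window 10 kb, step
1 kb; zero-GC windows are flagged and reported as 0) plus a per-base
cumulative skew. Inversion points are taken as the extremes of the
cumulative track after removing the circular drift and smoothing (5
windows) — equivalent to the sign changes of the windowed skew but robust
to window noise, which is why extremes rather than raw sign changes are
used. The parS cluster (largest single-linkage group with gap ≤ 100 kb,
center = circular median) breaks the two-fold ambiguity: the nearer
inversion is *ori*, the other (nearest the antipode) is *ter*. Without
parS hits the cumulative minimum is called *ori* and the result flagged
low-confidence.

**Coverage.** Tiled-window counts normalized to per-bp depth; the genome
median is the robust reference for coverage ratios.

**Secondary diagonal.** For each anti-diagonal class `k` (`i+j ≡ k mod N`)
the mean of `M[i,j]/E[s(i,j)]` over unmasked pairs with separation
> `min_separation` (default 10 bins), where `E[s]` is the genome-wide mean
at separation `s`. The profile is indexed by the genome position the
anti-diagonal reflects through (`k/2`) and rotated so *ori* is central.
Two properties follow from the geometry:

- a reflection axis of a circle crosses it at two antipodal points, so the
  profile repeats with period N/2; peak-position checks are made modulo
  N/2;
- the raw per-class means are exchangeable noisy values, so the profile is
  smoothed with a circular moving average (default width `max(5, N/20)`,
  forced odd, roughly twice the arm-alignment kernel scale). Null
  (strength-1) profiles are assessed on a seed-averaged profile; its max
  z-score stays below 3, while an implanted alignment of strength 3 gives
  a peak tens of standard deviations high, localized to ±2 bins.

The normalization of the profile's y-axis (genome-wide mean at matched
separations) is a declared choice of this package.

## Prophage 3D signatures

**Insulation.** `score[i] = log2(mean M over [i−w,i)×[i,i+w) / genome
mean)`, circular, window default 5 bins (25 kb at 5 kb resolution). Masked
bins inside the square mask the score. Borders are local minima with
topographic prominence ≥ 0.2 (circularized by triplication before peak
finding); NaN stretches are mean-filled for detection and never reported
as borders.

**Refinement.** Each predicted border snaps to the circularly closest
detected border within `max_shift` (default 20 kb — prophages are tens of
kb, farther borders belong to other structures); otherwise it is kept and
the side flagged. Statuses: refined / partial / unrefined / failed (order
inversion). Snapping to the nearest border makes refinement idempotent.

**Scores.** With interval bins `I` (k bins):

- `domain = mean(M[I×I], off-diagonal) / mean of the two adjacent k×k
  flanking squares`;
- `loop = M[b_first, b_last] / E[s(b_first, b_last)]`;
- `depletion = mean(M[I×F]/E[s])` over far bins `F` (circular distance
  > 2k from the interval; on matrices too small for that, the most distant
  available bins).

Note that ICE balancing absorbs part of a uniformly enriched block's
marginal excess into the biases, so the balanced-map domain contrast is
systematically below the raw enrichment (an implanted 2× block scores
≈ 1.3, verified against balancing the exact sampling weights — the
infinite-data limit). Thresholds are calibrated on balanced maps
accordingly.

**Classification.** CID-like requires `domain ≥ 1.5` *and* both refined
borders detected; loop requires `loop ≥ 2`; depletion requires
`depletion ≤ 0.67`; any label makes the prophage functional. These
thresholds are declared defaults of this package (the underlying
observations are qualitative); they live in the run configuration and are
echoed in every report header. In vitro/in vivo comparisons are expressed
as per-prophage score deltas after downsampling both maps to the common
total (antisymmetric by construction), not as categories.

## Virome quantification

A read counts toward a region iff its mapped start lies inside it
(start-based counting: unambiguous and depth-invariant).
`RPKM = reads/(total/10⁶)/(len/10³)` holds bit-exactly for every record.
Induction requires RPKM ≥ 10× the median RPKM of equally sized
prophage-free windows on the host. Junction calls require ≥ 5 pairs with
one mate starting within `edge_window` of the left border on the reverse
strand and the other ending within `edge_window` of the right border on
the forward strand — the orientation a read pair crossing the junction of
an excised circle must have; opposite-orientation edge pairs are tallied
separately as a diagnostic. The junction is the 5′-most left start and
3′-most right end. VLP totals sum induced prophage regions only (VLPs are
particles; whole-genome summation is available but not the default) and
are converted by `VLP = RPKM × PFU_spike / RPKM_spike`, then divided by
sample weight for VLP/g. Normalization uses reads mapped to the full
reference set (host + spikes), so the estimate is sequencing-depth
invariant.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis relies on:
power-law contact decay on a circle; CID segments with per-segment
enrichment (cross-segment contacts are the baseline, so insulation minima
appear at every boundary; a prophage segment enriched above its flanking
segments produces a scoreable CID square); an ori-anchored anti-diagonal
with an exponential kernel (width 2 bins — the real phenomenon's width is
not characterized, so the kernel is a modeling choice); induced-prophage
copy number applied per endpoint (`fold` per prophage end, `fold²`
within), which is exactly the scaling ICE removes, leaving raw coverage
elevated but the balanced map clean — matching how copy-number amplification
behaves in real balanced Hi-C; corner-loop enrichment on the border bin
pair; virome reads proportional to copy×length for induced prophages and
PFU×length for spikes, with exact junction-pair counts and uniform
host background outside prophages.

Not modeled: sequence errors and read-level simulation (alignments are
emitted directly), restriction-site chemistry and religation artifacts,
transcription-linked boundary effects, uneven mappability, spike recovery
biases, and the in vivo shift between short- and long-range contacts
(exposed only through the decay exponent α). Passing recovery tests
therefore demonstrates correctness of the computations on data with the
assumed structure, not robustness to every artifact of real libraries.

Default study conditions (used by the packaged demo and the recovery
measurements): a 2 Mb genome at 5–10 kb binning, 10⁶ contact pairs, 10⁵
virome read pairs of 35 bp, skew amplitude 0.2, three functional+induced
prophages (copy folds 10/5/4, loops 5/4/5, junction pairs 200/120/80) and
two cryptic ones, one spike of known PFU. Titer-recovery experiments
implant ~10⁸ VLP/g (3×10⁷ particles, 10⁷ PFU spike, 0.3 g sample) to match
the order of magnitude such samples show.

## Numerical and degenerate-input choices

- Division-by-zero guards: zero-GC windows report skew 0 with a flag;
  all-masked matrices, zero spike RPKM, zero genome median coverage and
  missing control windows raise informative errors.
- Peak/tie handling: border ties break toward the lower bin index;
  plateau minima are resolved by the peak finder's midpoint rule.
- The pipeline's NA policy: replicons with fewer than 5×10⁴ contacts get
  `NA` 3D calls instead of computed scores (too little signal for
  insulation or signature scoring).
- Reports carry a configuration hash (analysis parameters only, not the
  output path) and regenerate byte-identically from identical inputs.

## Known limitations

- Insulation border detection near the main-diagonal crossing of a strong
  secondary diagonal can emit spurious borders (a real structure, not
  noise); refinement is protected by `max_shift`, but border lists should
  be interpreted with the arm-alignment profile alongside.
- Cryptic prophages lying inside large background segments can have their
  intervals "refined" onto unrelated nearby borders; the functional call
  is unaffected, but refined coordinates of non-functional prophages are
  not meaningful.
- Duplicated-sequence stripe patterns and strong/weak signal grades are
  reported only through the raw scores; no categorical sub-classification
  is attempted.
- SCC is computed on linear diagonals; for strongly circular structure at
  separations near N/2 this slightly underweights wrap-around contacts.
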
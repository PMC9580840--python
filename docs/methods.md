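# Methods

## Profile model

A sequence of residues a₁…a_N is mapped through a hydropathicity scale
Ψ(aa) and smoothed with a centered moving average of odd width W:

    Ψ(i, W) = (1/W) Σ_{j=i−(W−1)/2}^{i+(W−1)/2} Ψ(a_j)

W = 9 means ±4 residues about the center, matching the segment convention
L = 2N + 1 of the fractal scale.  Edges are truncated, never padded: a
profile over a region of length L has L − W + 1 values, and no value is
emitted for a center whose window would overrun the region, because padded
values would fabricate extrema.  All positions are reported 1-based in the
coordinates of the full original sequence even when a sub-region (e.g. a
~350-residue motor domain) is analyzed, so peaks can be compared across
records and against published figure axes.  Window sums are accumulated
before the single division by W, so scales with integer values (MZ) yield
bit-identical means for identical windows.

## Scales

* **KD** — Kyte & Doolittle (1982), transcribed from the original table;
  hydrophobic residues positive (I = 4.5 … R = −4.5).
* **MZ** — Moret & Zebende (2007): Ψ(aa) is the exponent of the power-law
  decay of mean segment SASA with segment length, fitted on a log-log plot
  over 9 ≤ L ≤ 35.  Values are stored ×1000 (K = 69 … C = 246), the
  integer milli-unit form used in comparative profiling; this is an affine
  rescaling and every statistic here is affine-equivariant, so only the
  units of the reported deviation change.  Larger Ψ = faster occlusion
  with segment growth = more hydrophobic, so hydrophobic residues sit at
  profile maxima on both scales.

`fit_psi_exponent` performs the defining ordinary least-squares regression
of log SASA on log L, restricted to [l_min, l_max] = [9, 35] by default
(the self-similar range; both bounds are parameters).  It recovers
noise-free exponents to ≈ 1e−15 and is invariant to positive rescaling of
the SASA values (only the intercept shifts).  Re-deriving the MZ table
from Protein Data Bank structures is out of scope; the shipped values are
constants with the fitter available for user-supplied tables.

Nonstandard residue codes (B, Z, X, U, O) carry no scale value.  The
default policy is to raise an error naming the offending position, because
the level statistic is sensitive to peak heights; mean-imputation can be
opted into (`unknown="mean"`).

## Extrema and the level statistic

`find_extrema` reports interior extrema: positions strictly greater
(peaks) or less (valleys) than their nearest unequal neighbors, with flat
plateaus reduced to their center point (ties toward the smaller index, for
deterministic output).  Extrema of one kind closer than `min_separation`
residues are thinned keeping the more extreme one, iteratively
most-extreme first.  The default `min_separation` = 10 suits ~350-residue
domains profiled at W = 9, whose raw profiles jitter; it is a parameter.

`top_k_peaks` keeps the k (default 5) highest peaks, ties at the cutoff
broken toward the smaller position.  Fewer than k peaks is flagged rather
than hidden; no peaks at all is an error (an empty level set is reported,
not scored).  Hydrophilic minima are handled by the same machinery with
`polarity="valleys"`.

`level_deviation` scores the set by its deviation from the mean.  The
default definition is the mean absolute deviation (MAD about the mean);
the sample standard deviation (ddof = 1) is available as `"sd"`.  Published
comparative tables state only "deviation from the mean"; with user-fetched
motor-domain sequences both definitions can be computed side by side and
the one reproducing the published human value adopted — the acceptance
test does exactly this.  Both are affine-equivariant (deviation scales by
|a| under v → a·v + b) and MAD ≤ SD on any point set.

`level_members` finds the largest subset of peaks lying within ±ε of the
subset's own mean.  Sorted by value, an optimal subset can be taken
contiguous, so an exact O(k²) scan over value-sorted windows suffices; the
test suite verifies agreement with an exhaustive subset scan for k ≤ 8.
ε defaults to the peak set's MAD (self-scaling), since no fixed leveling
tolerance is canonical.

`window_sweep` operationalizes the optimal window W* as the deviation
minimizer over a window list (default 7, 9, …, 21), ties toward the
smaller window, with deviations equal within a 1e−9 relative tolerance
treated as ties so floating-point noise cannot break the tie rule.  This
is a reproducible operationalization of what is otherwise a judgment read
off stacked profile graphs.

`match_peaks` pairs peaks of two same-window, same-scale profiles by
greedy nearest-position matching within `max_shift`, closest pairs first,
each peak used once — supporting numbered-peak comparisons across species.

## Synthetic generator

The generator emulates the study condition the statistic targets: a
~360-residue domain whose W = 9 profile contains k = 5 well-separated
hydrophobic peaks at a common level with spread σ, over a hydrophilic
background.  Defaults: length 360, k 5, motif width 9, target level 220
and background 120 (MZ milli-units, i.e. a strongly hydrophobic level over
a mildly hydrophilic baseline), spacing ≥ 40 background residues between
motifs, σ = 0.

Mechanics: residues are split at the midpoint between background and
target levels; motifs draw only from the target side and the background
only from the `background_pool_size` (6) residues nearest the background
level on the other side.  Every motif residue therefore outvalues every
background residue, making each planted motif a clean local maximum and
keeping spurious background peaks well below the planted ones.  Each
peak's height h ~ N(target, σ²) is realized by a deterministic greedy
choice keeping every partial sum of the motif near j·h, so any window
inside the motif averages ≈ h.  Scale values are discrete, so requested
heights are quantized (granularity ≈ 1/W milli-units); the truth object
records *achieved* heights — the motif's mean scale value, identical to
the profile value at the center for W = motif width — making the truth an
exact oracle.  At σ = 0 the greedy choice yields the same motif at every
site, so the pipeline deviation is exactly zero up to float rounding.

What this does not emulate: real motor domains have autocorrelated
composition, peaks of unequal width and shape, and hydrophilic minima
structure; background here is i.i.d. from a narrow pool.  Passing the
recovery tests therefore shows the pipeline is correct and sensitive to
peak-height spread, not that any particular biological family exhibits
level sets.

## Problem sizes and determinism

The stochastic recovery check uses 50 replicates per spread
σ ∈ {0, 0.25, 0.5, 1, 2} at length 360 — enough for stable medians while
keeping the whole suite fast.  The exhaustive extremum check enumerates
all ≈ 8·10⁵ profiles of length ≤ 12 over a 3-value alphabet against a
naive oracle.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); fixed seeds give byte-identical sequences.

## Limitations

* Published per-species deviations can only be reproduced with the
  original UniProt motor-domain sequences, which are not redistributable
  and whose exact domain boundaries are not printed; results on real
  sequences shift with the chosen region.
* The MAD-vs-SD choice is resolved empirically against a published value,
  not derivable from first principles.
* Peak matching is greedy, not globally optimal; for profiles with dense
  ambiguous peaks an assignment solver would differ.
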
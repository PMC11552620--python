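# Methods

## Model

A whole-genome-sequencing k-mer spectrum tallies, for each coverage *c*, the
number *f*(*c*) of distinct k-mers occurring exactly *c* times in the reads.
For a polyploid of ploidy *p* with per-haplotype k-mer coverage
*C*<sub>het</sub>, the genomic part of the spectrum is modelled as a
superposition of *p* normal components,

  *f̂*<sub>*i*</sub>(*c*) = *A*<sub>*i*</sub> exp(−(*c* − *μ*<sub>*i*</sub>)² / 2*σ*<sub>*i*</sub>²),  *μ*<sub>*i*</sub> ≈ *i C*<sub>het</sub>,

one per sharing class: component *i* collects the k-mers present on exactly
*i* homologous chromosomes.  The normal shape is an approximation to the
Poisson/negative-binomial coverage law that becomes accurate at the
coverages where size estimation is attempted (*C*<sub>het</sub> ≳ 20);
symmetric normals are used deliberately — skewed component families are out
of scope.

Sizes follow from instance counting.  A k-mer seen *c* times contributes *c*
instances; a region of *L* distinct k-mers in class *i* contributes
≈ *L·i·C*<sub>het</sub> instances, so

  *g*<sub>*i*</sub> = Σ<sub>*c*</sub> *c·f̂*<sub>*i*</sub>(*c*) / (*p C*<sub>het</sub>) = *L·i*/*p*

is that class's share of the *average haploid* genome size.  Residual mass
after all *p* subtractions is attributed to repeats
(*g*<sub>*p*+1</sub>), and *G* = Σ<sub>*i*=1..*p*+1</sub> *g*<sub>*i*</sub>,
full size *G·p*.  Distinct-k-mer counts are treated as base counts
(*L* − *k* + 1 ≈ *L*); no formula uses *k* itself, which is carried as
metadata only.

## Pipeline and numerical choices

**Error cutoff.**  Sequencing errors produce a spike of low-coverage k-mers
adjacent to the y axis.  The spectrum (smoothed by a centred moving average,
default width 5, with edge bins normalized by the number of real terms) is
followed down from coverage 1; the coverage at which it first turns upward
is the cutoff, below which bins are zeroed.  Non-strict descent means a flat
run of empty bins still counts as descending, so sparse spectra behave.  If
the spectrum rises immediately there is no error peak and nothing is
excluded; if it never rises in the lower half of the range, no genomic peak
is discernible and the cutoff falls back to 1 with a warning.  This
descent-then-rise rule, rather than "first local minimum anywhere", is what
prevents the valley *between two genomic peaks* from being mistaken for the
error valley on clean spectra.

**Initial C_het.**  The user supplies a coverage hint *C* with
2 *C*<sub>het</sub> < *C* < 3 *C*<sub>het</sub>; the smoothed argmax inside
the open interval (*C*/3, *C*/2) initialises *C*<sub>het</sub>.  If no bin
there reaches 5% of the tallest non-error bin (a homozygous-like spectrum
with no first peak), the global non-error argmax divided by the integer that
places the quotient inside the interval is used instead, with a warning.
For *p* = 1 the bracket degenerates — the only peak *is* *C*<sub>het</sub> —
so the global non-error argmax is taken directly.

**Scale, fill, fit, subtract.**  Each component *i* is fitted inside the
window *i C*<sub>het</sub> ± *w*, *w* = 0.5 *C*<sub>het</sub>, so adjacent
windows touch without overlapping.  Within the window the residual spectrum
is max-normalized (raw counts span many orders of magnitude across species;
the optimizer works on [0, 1] and the factor inverts exactly), and absent
integer coverages are filled by linear interpolation between present
neighbours (zeros beyond the outermost present bins — no extrapolation).
Bounded least squares (scipy `curve_fit`, trust-region reflective) fits
(*A*, *μ*, *σ*) with *μ* confined to the window, *σ* ∈ (0, *w*], *A* ≥ 0;
initialisation *μ*₀ = *i C*<sub>het</sub>, *σ*₀ = *w*/2, *A*₀ = the scaled
residual at the bin nearest the centre.  The fitted curve is evaluated on
the full coverage grid at raw scale and subtracted with flooring at zero.
Degenerate windows (empty, all-zero) and optimizer failures yield a flat
component with `converged = False` — never an exception mid-pipeline.
After the *i* = 1 fit, *C*<sub>het</sub> is replaced by the fitted *μ*₁ and
frozen (later windows are centred at multiples of it), unless the first
component carries less than 0.1% of the post-cutoff k-mer instances, in
which case the spectrum is flagged homozygous-like and the initial estimate
is kept.

**Joint refinement.**  The sequential pass is a greedy decomposition: a
small component sitting on the flank of a much larger neighbour can absorb
that flank, and the neighbour's own fit then over-predicts the depleted
region.  A single joint re-fit of all *p* components (sum of Gaussians, same
per-component bounds, initialised from the sequential estimates) removes
this coupling.  Residuals where the fitted sum exceeds the observed counts
are weighted by a factor of 3 (`overshoot_penalty`): over-prediction is
physically meaningless, since more k-mers cannot be subtracted than were
observed, and steering the summed curve to sit at or below the data keeps
the flooring losses of the final subtraction far below 1% of the total
instances.  Refinement is on by default and can be disabled
(`joint_refine=False`) to inspect the raw sequential behaviour.

**Accounting.**  The final residual is
max(0, observed − Σ fitted curves); the floored mass is retained in the
report, so fitted + residual = observed + floored holds to machine
precision and conservation can always be audited.  The repeat sum uses all
residual mass at or above the error cutoff by default; a stricter policy
(`above_last_window`) restricts it to coverages beyond the last fitting
window.  A counter's aggregate ceiling bin (final bin > 10× the median of
its ten predecessors) is flagged on parse and excluded from fitting and
sums by default.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window_half_width_factor` | 0.5 | fitting window half-width as a fraction of C_het (≤ 0.5 keeps windows non-overlapping) |
| `smoothing_window` | 5 bins | moving-average width for valley/peak detection; 1 disables |
| `min_peak_prominence` | 0.05 | fraction of the tallest non-error bin a first peak must reach |
| `min_component_mass_fraction` | 1e-3 | instance share below which the i=1 fit is deemed empty (homozygous fallback) |
| `overshoot_penalty` | 3.0 | asymmetric weight on fitted-above-observed residuals in the joint refinement |
| `exclude_aggregate_bin` | true | drop the counter's ceiling bin |
| `repeat_min_coverage_policy` | `above_error_cutoff` | lower bound of the repeat sum |

## Synthetic data

`simulate_histogram` draws a spectrum directly from a mixture description:
class *i* coverages are Poisson (or negative-binomial with overdispersion θ,
variance *m* + *m*²/θ) around *i C*<sub>het</sub>, error k-mers get
geometrically decaying coverages from 1, repeat k-mers cluster around a
configurable multiple of *C*<sub>het</sub>.  Draws of zero are clamped to 1
so the distinct-k-mer total is exact.  `expected_G_oracle` computes the
target size by arithmetic alone — Σ *L*<sub>*i*</sub>·*i*/*p* plus the
repeat contribution — and never touches the estimator, so accuracy tests
compare two independent routes.

`simulate_polyploid_reads` goes end to end at desk scale (haplotypes up to
1 Mb): one random ancestral sequence, *p* homologs by i.i.d. per-site
substitutions (no indels, keeping the truth computable), uniform forward-
strand reads with i.i.d. base errors, and exact canonical k-mer counting
(lexicographic min of a k-mer and its reverse complement, 2-bit-packed into
uint64 words — the convention of standard counters).  Its recorded truth is
the haplotype length and the k-mer coverage
depth·(read_len − *k* + 1)/read_len.

What the generators do *not* emulate: real base-composition and GC bias,
read-quality profiles, indels, structured repeats, organellar contamination,
and counter-specific artifacts beyond the ceiling bin.  Passing tests
demonstrate correct decomposition and size arithmetic under the stated
coverage laws, not robustness to every artifact of a real sequencing run.
Note one deliberate subtlety: read errors thin the genomic k-mer coverage by
(1 − e)^*k*, so the spectrum's C_het sits below the error-free value; the
estimator and its instance sums are self-consistent under that thinning,
which is why genome sizes remain accurate even though the recorded true
C_het refers to error-free reads.

## Problem sizes used in the checks

The bundled accuracy sweep uses twenty Poisson mixtures with ploidy in
{2, 4, 6, 8}, C_het in [20, 60] and 1–5 × 10⁵ distinct k-mers per class;
the read-level check simulates a 300 kb tetraploid haplotype at 30× depth
(2% homolog divergence, 0.5% read error, k = 17).  These sizes give sampling
noise well below the tolerances being checked while keeping a full run in
tens of seconds.

## Known limitations

- Symmetric normal components bias fitted means slightly below the true
  Poisson mean (the Poisson is right-skewed); the effect on C_het is under
  1% at C_het ≥ 20 but grows at lower coverage.
- Class sizes *g*<sub>*i*</sub> for heavily overlapping adjacent peaks (low
  C_het, high *i*) trade mass with their neighbours; their *sum* remains
  accurate because every observed instance is counted exactly once.
- The repeat estimate absorbs all unfitted residual above the cutoff,
  including fit error, so it is the least sharp of the reported sizes.
- Ploidy must be supplied; it is not inferred from the spectrum.
- Heterozygosity rate, GC bias and skewed/overdispersed component families
  are out of scope.
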
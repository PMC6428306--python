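# Methods

## Signal model and assumptions

The predictor treats a DNA sequence as a unit-spaced discrete signal
and exon finding as detection of three-base periodicity (TBP): inside
coding sequence, codon-usage bias makes the marginal base composition
depend on the codon position, which puts a spectral line at 1/3
cycles/nucleotide; intron background is modelled as aperiodic noise.
The method is training-free and strand-symmetric (the A/T and C/G pairs
share an encoded value, and a reverse complement yields the reversed
score track).  It does not model splice-site motifs, reading-frame
phase, or frame shifts between neighbouring exons — it measures
periodicity strength, not gene structure.

All continuous-time filter definitions are discretized at one sample
per nucleotide; integrals become sums.  Windowed sums use zero padding
at the sequence ends, and positions within half the largest filter
support of either end (200 nt at the defaults) are reported as
edge-affected in the output manifest.

## Pipeline and parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `L` | 2400 | base filter length (samples); with the scale grid below it yields exon-sized effective windows |
| `m` | 6 | B-spline order of the analysis window; order 6 trades main-lobe width against side-lobe leakage |
| `J` | 10 | number of scales |
| `a_min`, `a_max` | 1/60, 1/6 | geometric scale grid; effective supports `round(L·a)` = 40…400 nt, bracketing typical exon lengths |
| `omega0` | 2π/3 rad/sample | modulation frequency, the TBP line; a modulated window of any width stays tuned to 1/3 cycles/nt |
| `tau0` | 3 nt | AMDF lag; 3 targets period-3 structure |
| `resonator_radius` | 0.992 | pole radius of the zero-phase two-pole resonator at 2π/3; closer to 1 = narrower band but longer ringing (~1/(1−r) ≈ 125 nt) |
| `range_mode` | `direct` | see below |

**Scale convention.**  Scale `a` *compresses* the base window: taps at
scale `a` occupy `round(L·a)` samples (round half up; even supports use
the half-sample-shifted centered grid).  This is the only reading under
which a 2400-sample base filter and scales in [1/60, 1/6] jointly give
exon-sized (40–400 nt) windows.

**Normalization.**  Domain and range coefficients are divided by the
window mass at each scale, so a unit-amplitude period-3 tone responds
identically (±5%) at every scale.  That calibration deliberately does
*not* equalize noise: averaging fewer samples leaves the white-noise
floor ~3× higher at the smallest scale than at the largest.  Because
the final spectrum sums squared products over all scale pairs, the sum
would otherwise be dominated by the noisiest pairs; a per-scale
standardization step (each scale's bilateral coefficients divided by
their median magnitude — a robust noise proxy, as intron-like
background occupies most positions) therefore sits between the
bilateral combination and the products.  This is the same
noise-referenced calibration that multiscale-product denoising schemes
use before multiplying scales.  On the validation suite it raises the
pooled nucleotide AUC of the product spectrum from 0.78 to 0.85.

**Range-filter orientation.**  The windowed lag-3 AMDF is formally a
dissimilarity — zero on a perfectly 3-periodic signal — so one might
expect it to need inversion before entering the bilateral product.
Empirically the opposite holds: the resonator passes only the 2π/3
band, its output amplitude is much larger inside exons, and the lag-3
difference of a narrowband signal scales with that amplitude, so the
direct AMDF already tracks the period-3 envelope and peaks inside
exons.  Both orientations are implemented (`range_mode`); `direct` was
selected on the synthetic validation suite (higher AUC, exon-peaked
score tracks) and ships as the default.  The resonator is applied
forward–backward (zero phase) so exon boundaries are not shifted; it
feeds only the range branch.

**Approximate correlation convention.**  Any of the four conditional
ratios with a zero denominator is dropped and the mean is taken over
the remaining ones (the convention of the metric's original
nucleotide-accuracy definition).  Note that at degenerate thresholds
(everything called exonic, or nothing), the surviving ratios are far
from 1/2 and AC is pushed to ≈ ±1/3 even for a chance-level track; AC
is only a meaningful chance-level diagnostic at thresholds where all
four ratios are defined, and chance-level analyses in the test suite
restrict themselves to those.

**Inter-scale JS analysis.**  Histograms use 100 shared equal-width
bins spanning the pooled exon∪intron magnitude range of each adjacent
scale pair; JS divergence uses log base 2 (bounded in [0, 1]).  The
analysis defaults to the domain-branch magnitudes `|U_d|`: the question
it answers is whether the *multiscale decomposition* of exon structure
is stable across scales while noise is not, and the range envelope's
own scale-dependent distribution shape would confound that comparison
(with the bilateral or range coefficients selectable via `component`).
On the validation suite the exon-position JS is smaller than the
intron-position JS for 6 of 9 adjacent pairs, with both in the 1e-2
range.

## Synthetic data

The generator emulates the TBP premise directly: intron background is
iid uniform A/C/G/T (optionally a mildly persistent first-order Markov
chain), and exon regions are concatenated codons drawn from the mixture
`(1 − bias)·uniform + bias·skewed`, where the skewed 64-entry codon
table is an outer product of per-position Dirichlet(0.5) draws
re-sampled until the three codon positions prefer three distinct bases.
Position-specific composition — not a pure sinusoid — is what creates
the 1/3-frequency line in real coding sequence, so planted exons carry
realistic, noisy periodicity.  `bias = 0` collapses exons to iid
uniform bases, statistically identical to the intron background, which
is the chance-level control.

The canonical validation suite is 50 sequences of 6 kb with two planted
exons each, lengths cycling through the ten evaluation length classes
(1–24 … 300–600 nt), bias 0.8, exons separated by at least the largest
filter support (400 nt) from each other and from the sequence ends.
These sizes keep every end-to-end check within seconds while giving ten
exons per length class.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate — includes: splice-site motifs and real
exon/intron length distributions; isochore/GC heterogeneity;
*structured* intron noise such as tandem repeats or locally biased
composition, which in real genomes produces spurious period-3 patches.
That last omission matters for interpreting one result below.

## Validation results and a negative finding

On the canonical suite, 93% of planted exons of length ≥ 75 nt carry a
local score maximum above the 90th percentile of intron scores within
20 nt of the exon; the exon/intron mean-magnitude contrast is larger
for adjacent-scale products than for single-scale coefficients at all
9 scale pairs (ratios ≈ 5.3 versus ≈ 2.5); and the adjacent-scale JS
pattern behaves as described above.

A directional claim that does **not** hold under these conditions: the
nucleotide-level AUC of the product spectrum does not exceed the AUC of
the best single-scale bilateral track on ≥ 90% of sequences (observed:
~4%; mean 0.84 versus 0.90).  With iid intron background, ranking
quality rises monotonically with window size, so an oracle-selected
largest scale is close to unbeatable, and summing squared products over
all pairs necessarily mixes in noisier small scales.  The
noise-dilution advantage of multiscale products targets
scale-*incoherent structured* noise, which the iid background by
construction lacks.  The corresponding test is kept as specified and
fails honestly; the amplitude-contrast half of the claim passes.
Similarly, the chance-level control's per-range AC stays near zero but
its extreme over ~1000 correlated (range, threshold) cells reaches
≈ 0.13 rather than < 0.1: the 400 nt correlation length of the score
track leaves only ~10 effectively independent exons per length class.

## Numerical choices and degenerate inputs

* Same-length correlation uses FFT convolution; every stage is verified
  against direct double-loop summation to 1e−10 absolute.
* The B-spline window is evaluated from the closed-form alternating
  sum, clipped at tiny negative round-off, symmetrized exactly, and
  peak-normalized; order 1 is special-cased to the box.
* An all-zero spectrum normalizes to all-zero scores (no 0/0).
* Sequences shorter than the largest filter support are rejected with
  the minimum length in the message (the CLI reports these per record
  and exits with a distinct code).
* ROC thresholds are the reversed ascending `linspace(0, 1, n)` grid so
  that scores quantized to the same grid compare bit-for-bit.
* Ambiguity codes map to 0 (neutral in both filter branches) and are
  counted in a log warning.

## Known limitations

Microexons (< 25 nt) are essentially undetectable — too few periods
fall inside even the smallest 40 nt window; best AC in the shortest
class is near chance on synthetic data.  Scores near sequence edges are
attenuated by zero padding.  The predictor emits a score track, not
exon calls; interval calling is left to threshold sweeps on the
evaluation side.  Performance numbers quoted here are synthetic-suite
measurements and transfer to real genomes only to the extent the
generator's assumptions do.
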
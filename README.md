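# exonmsbf

Per-nucleotide exon prediction for eukaryotic DNA from **three-base
periodicity** (TBP), using a non-linear **multiscale bilateral filter**
whose adjacent-scale coefficient products amplify coding structure and
dilute intron noise.

Coding regions carry a statistical period-3 pattern — codon-usage bias
makes the base composition depend on the position within the codon —
visible as a power-spectrum line at *f* = 1/3 cycles/nucleotide.
Intron background lacks it.  `exonmsbf` scores every nucleotide of a
sequence by the local strength of that pattern, without any training or
prior gene models, which makes it applicable to novel genomes.  It is
aimed at people building or benchmarking signal-processing gene-finding
pipelines: alongside the predictor it ships the full evaluation stack
(approximate correlation stratified by exon length, ROC/AUC,
inter-scale Jensen–Shannon analysis) and a deterministic synthetic-data
generator, so the whole system is testable offline.

## Method

For a DNA sequence of length *N*:

1. **Numerical encoding.** Bases map to the paired-numerical signal
   *u*: A,T → +1 and C,G → −1 (ambiguity codes → 0).  Paired bases
   share a value, so the track is strand-symmetric.
2. **Domain filter.** At each of *J* = 10 scales *a_j* (geometric from
   1/60 to 1/6 of the base length *L* = 2400, i.e. effective windows of
   40…400 nt), *u* is correlated with a B-spline window of order 6
   modulated by `exp(i·2π/3·k)`:

       U_d(b, a_j) = Σ_k u(b+k) · (1/a_j) β_6(k / (L a_j)) · e^{i 2π k/3}

   a wavelet-style transform tuned to the TBP frequency, normalized per
   scale by the window mass so a unit period-3 tone responds equally at
   every scale.
3. **Range filter.** *u* is passed through a zero-phase two-pole
   resonator centered at 2π/3 (pole radius 0.992), and the lag-3
   average magnitude difference function (AMDF) of the result,
   `d(t) = |ũ(t) − ũ(t−3)|`, is averaged under the same windows,
   giving a per-position measure U_r of local period-3 activity.
4. **Bilateral product.** `U = U_d · U_r` — a non-linear filter
   combining positional weighting with value-similarity, which
   preserves short exons and exon–intron boundaries better than linear
   filtering alone.
5. **Multiscale products.** After putting all scales on a common noise
   footing (median standardization), adjacent-scale magnitudes are
   multiplied, `MP_j(b) = |U(b,a_j)|·|U(b,a_{j+1})|`: exon structure is
   coherent across scales and survives the product; scale-incoherent
   noise is suppressed.
6. **Spectrum.** `S(b) = Σ_j MP_j(b)²`, max-normalized to the final
   score track `Sp(b) ∈ [0,1]`.

Evaluation uses nucleotide-level confusion counts under a 101-point
threshold sweep, the approximate correlation
`AC = 2·(¼(TP/(TP+FN) + TP/(TP+FP) + TN/(TN+FP) + TN/(TN+FN)) − ½)`,
sensitivity/specificity with trapezoidal AUC, best AC per exon-length
class (ten classes from <25 nt to ≥300 nt), and Jensen–Shannon
divergence (log base 2) between adjacent-scale coefficient histograms
of exon versus intron positions.

See `docs/methods.md` for assumptions, parameter rationale and known
limitations.

## Worked example

Simulate two 4 kb sequences with two planted codon-biased exons each,
score them, and evaluate against the truth:

```sh
cat > sim.yaml <<EOF
n_sequences: 2
seq_length: 4000
exons_per_sequence: 2
exon_lengths: [150, 300]
bias_strength: 0.8
seed: 11
EOF
exonmsbf simulate --config sim.yaml --out-prefix demo
exonmsbf predict demo.fasta --out-prefix demo
exonmsbf evaluate demo.tsv --bed demo.bed --out report.json
```

`demo.bed` holds the planted truth (e.g. `synth_11_000  1347  1497`),
`demo.bedgraph` / `demo.tsv` the per-nucleotide scores in [0, 1], and
`report.json` the metrics; for this run:

```
AUC: 0.806
AC by range: {'[150,175)': 0.434, '[300,inf)': 0.53}
```

i.e. the score track separates exon from intron nucleotides with AUC
0.81, and the best threshold reaches approximate correlation 0.43 for
the planted 150 nt exons and 0.53 for the 300 nt exons.  Every command
also writes a `*.manifest.json` (config hash, input checksums, seed)
sufficient to reproduce the run exactly.

The same pipeline is available as a library:

```python
from exonmsbf import SpectralConfig, predict, read_fasta

record = read_fasta("demo.fasta")[0]
track = predict(record, SpectralConfig())   # track.Sp: scores in [0, 1]
```

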
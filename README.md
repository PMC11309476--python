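# nucleotype

Genome size is more than a bookkeeping number: through its effect on
nuclear and cell volume it constrains how fast a cell can divide, and —
for planktonic algae such as diatoms — where in the ocean it thrives.
`nucleotype` implements the full computational chain needed to study these
links at the species level:

- **Genome-size estimation** from sequencing-depth spectra: the k-mer peak
  formula `GS = N / (C·p)` with multi-k averaging, and the Lander–Waterman
  coverage formula `GS = L·N / C` with a robust half-sample modal coverage.
- **Trait construction**: geometric cell biovolumes (cylinder, sphere,
  prolate spheroid, with height-from-diameter fallback rules), maximum
  growth rate by the linear method on log fluorescence, doubling time
  `T_d = ln 2 / µ`, and the standard transformations (log₁₀, arcsin √p).
- **Phylogenetic comparative statistics**: Brownian covariance matrices
  from ultrametric trees, Pagel's λ signal with a likelihood-ratio test,
  PGLS with maximum-likelihood λ, Spearman and Wilcoxon rank statistics
  with exact small-sample p-values.
- **Phylogenetic path analysis**: d-separation basis sets, PGLS-based
  conditional-independence tests, Fisher's `C = −2 Σ ln p`,
  `CICc = C + 2qn/(n−q−1)` ranking, standardized path coefficients, and
  full/conditional model averaging over a shipped 14-model registry.
- **Abundance modelling**: long OTU tables → species-level relative
  abundances → a Bayesian gamma regression with a log link, a
  genome-size × environment interaction (temperature, ocean region, or a
  latitude spline), and phylogenetically correlated species intercepts,
  fitted by a seeded adaptive MCMC sampler with split-R̂ convergence checks,
  credible-interval significance calls, Bayesian r², and interaction
  predictions at 0/10/20/30 °C.
- **Synthetic data** for every stage — seedable generators for trees,
  DAG-structured phylogenetic traits, k-mer/coverage spectra, growth
  curves, and abundance tables — so the whole pipeline is testable without
  any downloads.

The library is the primary interface (see `examples/`); a thin `nucleotype`
CLI wraps it (`simulate`, `genomesize`, `traits`, `signal`, `pgls`,
`pathfit`, `abundance`, `run`) for file-based pipelines, and
`nucleotype run --config cfg.yaml` executes the staged pipeline with a
provenance manifest.

## Worked example

Estimate a genome size from simulated 40× sequencing of a 1 Mb genome
(`examples/01_genome_size_from_spectra.py`):

```text
k=17: peak depth 40, error cutoff 5, GS = 1.000 Mb
...
multi-k average: 1.013 Mb
coverage method: modal coverage 35.4x, GS = 0.988 Mb
```

Both estimators land within ~1–2% of the true 1 Mb: the k-mer route counts
genomic k-mer mass above the error cutoff and divides by the spectrum peak;
the coverage route divides total mapped bases by the modal per-contig
coverage. Their small disagreement is the cross-method spread you should
expect on real data.

Measure phylogenetic signal and fit a PGLS on traits simulated with known
effects (`examples/03_signal_and_pgls.py`):

```text
Pagel's lambda for genome size: 1.000 (LR = 85.2, p = 2.72e-20)

             coef      se        t       p
intercept -0.0146  0.2496  -0.0584  0.9535
GS         0.6605  0.0551  11.9855  0.0000
TEMP      -0.4894  0.0686  -7.1334  0.0000

ML lambda = 1.000, r^2 = 0.660, n = 100
```

The trait was generated under pure Brownian motion (λ = 1) with
standardized effects 0.5 (genome size) and −0.5 (temperature) on doubling
time; λ̂ = 1.000 recovers the signal and the slopes straddle the generating
values within sampling error for a single 100-tip tree.

The other examples cover growth/volume traits (`02`), the 14-model path
analysis with CICc ranking and model averaging (`04`), the Bayesian gamma
abundance model with its temperature × genome-size interaction (`05`), and
OTU-table processing (`06`).

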
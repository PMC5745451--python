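# boolstab

Boolean-network stability analysis of signaling pathways from short gene
expression time series.

Biological pathways are thought to buffer internal and external
perturbations, and this buffering can degrade with age. `boolstab`
quantifies such changes from a two-group (e.g. young vs aged) expression
time series in three data-driven steps:

1. **Binarization.** Each gene's real-valued series is thresholded with a
   step-function procedure: the sorted values define an initial step
   function, dynamic programming finds the optimal step function for every
   number of discontinuities, and the threshold is placed at the strongest
   discontinuity (median-voted across all step-function depths). A seeded
   bootstrap test keeps only genes that are *significantly binarizable*
   (p < 0.05); one threshold per gene is shared by all samples of both
   groups, and the group split happens after binarization.
2. **Network inference.** For each group, candidate Boolean update rules
   are inferred per gene by best-fit extension of partially defined
   Boolean functions: regulator sets X′ of size k = 0..`max_k` are scored
   by the error ε = Σ_patterns min(|T(s)|, |F(s)|), where T and F collect
   input patterns observed before a 1 or a 0 of the target; all
   smallest-cardinality minimal-error sets are kept and their unobserved
   truth-table entries expanded into concrete candidate functions. The
   per-gene candidate lists form a probabilistic-Boolean-network-style
   ensemble with equal weight per function.
3. **Stability measurement.** Concrete synchronous networks
   x(t+1) = (f₁(x(t)), …, fₙ(x(t))) are sampled uniformly from each
   group's ensemble. For each network, random start states (uniform,
   successors of uniform draws, or members of attractors reached from
   uniform draws) receive a temporary single-bit flip; after h ∈ {1, 5}
   synchronous transitions the damage is the normalized Hamming distance
   Hₙ(x, x′) = (1/n) Σᵢ |xᵢ − x′ᵢ| between the perturbed and unperturbed
   trajectories. Per-network mean damages are summarized (min/max/mean)
   per start-state class and horizon, and the two groups are compared
   with a two-sided Wilcoxon rank-sum test.

A synthetic-study generator produces ground-truth networks, binary
trajectories, and microarray-like two-group expression matrices, so every
stage is testable end to end without downloading data. A curated
22-gene NF-κB signaling panel (Entrez IDs) ships as
`boolstab/data/nfkb_panel.tsv`, and `boolstab.pipeline.fetch_gse362`
can fetch the public GEO series matrix GSE362 (human skeletal muscle,
young and aged healthy males) when network access is available.

## Worked example

```python
from boolstab import (SyntheticStudySpec, generate_study,
                      PipelineConfig, PerturbationConfig, run_study)

bundle = generate_study(SyntheticStudySpec(n_constant_aged=4, seed=7))
cfg = PipelineConfig(
    perturbation=PerturbationConfig(n_networks=100, n_states=100, seed=7),
    seed=7,
)
report = run_study(bundle.expression, bundle.sample_sheet, cfg=cfg)
counts = report.manifest["counts"]
print("retained:", counts["genes_retained"])
print("dependencies:", counts["dependencies"])
print(report.summaries["aged"].summary_frame().round(4))
```

prints

```
retained: 22
dependencies: {'young': 62, 'aged': 53}
               h1                      h5
              min     max    mean     min     max    mean
random     0.0241  0.0495  0.0361  0.0205  0.1045  0.0567
successor  0.0218  0.0536  0.0367  0.0209  0.1005  0.0560
attractor  0.0245  0.0486  0.0352  0.0132  0.0914  0.0534
```

Of 86 simulated genes, 22 pass the binarizability filter. The aged
ensemble (which had 4 constant-zero genes planted) loses dependencies
relative to the young one (53 vs 62), and its mean damage after five
transitions (≈ 0.055) clearly exceeds its one-transition damage
(≈ 0.036): perturbations keep spreading instead of healing. Comparing
the per-network damage distributions of the two groups
(`report.comparison`) gives rank-sum p-values below 10⁻⁵ for every
start-state class at horizon 5.

The same pipeline runs from the shell:

```sh
boolstab synth --n-genes 86 --n-binarizable 22 --seed 7 -o study/
boolstab run study/expression.tsv study/samples.tsv -o report/
```

For real data, pass your own genes × samples TSV (columns in time order)
and a sample sheet with `sample`, `group`, `age` columns; duplicate gene
rows are collapsed by geometric mean and duplicate-age samples by
arithmetic mean before binarization.

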
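# rumen-culturomics

Analysis toolkit for **dilution-to-extinction culturomics** experiments:
quantifying how much of a dense microbial community (the motivating system is
the cow rumen) can be grown on agar plates, and what kind of taxa the plates
recover.

The experimental design it models: a rumen fluid sample is serially diluted
(10⁻¹ … 10⁻⁶) and each dilution is plated in duplicate on two media — a
chemically **defined** medium and an **undefined** medium supplemented with
clarified rumen fluid. The original sample, every dilution, every plate wash,
and a cohort of additional rumen microbiomes are 16S-sequenced into one OTU
table. The package answers, from that table plus sample metadata:

* **Cultivability accounting** — the seven-way Venn partition of OTUs across
  {rumen community, defined plates, undefined plates}; the cultivable
  fraction (shared OTUs / rumen OTUs); the richness gained by adding a second
  medium; the per-dilution overlap between each diluted aliquot and its
  plates.
* **Rare biosphere** — plate-detected OTUs never seen in the rumen sample or
  its dilutions, surveyed for detection frequency across the cohort.
* **Phylogenetic cohesion** — is the cultured set phylogenetically tighter
  than a size-matched random subset of the community? Mean-pairwise-distance
  permutation test, globally and per family, on patristic, p-distance, or
  precomputed distance matrices.
* **Community structure** — rarefaction to even depth, PCoA of Euclidean
  distances on relative abundances, and a two-way PERMANOVA (medium ×
  dilution) with sequential sums of squares.
* **Richness statistics** — exact Wilcoxon signed-rank and rank-sum tests,
  Kruskal–Wallis, Holm–Bonferroni adjustment.
* **Abundance–cultivability correlation** — OTUs binned into abundance
  percentiles; Pearson correlation of cultured-OTU counts per bin against
  bin abundance, per dilution and cultured subset.

Because the real experiment's raw reads are not bundled, the package ships a
**ground-truthed simulator** of the entire experiment (log-normal community,
Brownian cultivability on a simulated Yule phylogeny, Poisson founder
sampling of plates, multinomial sequencing). Every analysis can therefore be
validated against known truth.

## Quick start

Simulate an experiment and analyze it in one step:

```bash
culturomics run --simulate --seed 1 --out-dir results/
```

which prints a headline summary like

```
cultivable: 81% (1156 of 1421 rumen OTUs on plates)
medium gain: up to 24% (adding undefined medium)
rare biosphere: 313 OTUs
  never detected in cohort: 0% of them (over 38 microbiomes)
phylogenetic cohesion: cultured MPD at percentile 100.0 of the null (p_lesser=1)
PCoA: axis1 37.4%, axis2 25.9% of variance
PERMANOVA medium: R2=0.101 p=0.05495
PERMANOVA dilution: R2=0.250 p=0.1019
```

and writes `results.json` (all raw fractions and test results),
`pcoa_coordinates.tsv`, and `rare_biosphere_survey.tsv`. (On default
simulations ~80 % of the community is cultivable, which puts the cohesion
test in a degenerate, powerless regime — see `docs/methods.md` §4 and §7.)

To analyze real data, point the pipeline at files instead:

```bash
culturomics run \
  --table otu_table.tsv --metadata metadata.tsv \
  --tree otus.nwk --taxonomy taxonomy.tsv \
  --out-dir results/
```

* `otu_table.tsv` — integer counts, OTUs as rows, samples as columns, first
  header cell `otu_id`.
* `metadata.tsv` — columns `sample_id`, `source` (`rumen`/`plate`/`cohort`),
  `medium` (`defined`/`undefined`/`none`), `dilution_exponent`, `replicate`.
* distances for the cohesion test come from `--distances` (TSV matrix),
  `--alignment` (aligned FASTA → p-distances), or `--tree` (Newick →
  patristic), in that precedence.

Other subcommands: `culturomics simulate` writes a synthetic experiment with
its ground truth; `culturomics phylotest` runs the cohesion test standalone.

## Library use

```python
from culturomics import (
    SimulationParams, simulate_experiment,
    filter_low_count_otus, partition_otus, cultivable_fraction,
)

bundle = simulate_experiment(SimulationParams(seed=1))
filtered = filter_low_count_otus(bundle.table, max_total=2)
part = partition_otus(filtered, bundle.metadata)
print(cultivable_fraction(part))      # 0.8135...
print(part.cardinalities())
```

See `docs/methods.md` for the statistical methods, the simulator's generative
model, and every default parameter with its rationale.

## Conventions

* Percentages in summaries are **truncated** to whole percents (686/2881 →
  23%, never 24%); one-decimal percentages use banker's rounding on the
  decimal representation (61/1698 → 3.6%).
* Set-level accounting always runs on the low-count-filtered but
  **non-rarefied** table; rarefied tables are used only for ordination and
  richness tests.
* All randomness flows from named `numpy` SeedSequence substreams, so every
  result is exactly reproducible from the seed.
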
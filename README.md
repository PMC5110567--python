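# barcodegap

Evaluation of DNA barcode markers for species identification: barcoding-gap
analysis, neighbor-joining trees with bootstrap, and discrimination rates
for single markers and multi-locus combinations.

## The problem

DNA barcoding identifies species from short standardised loci — in plants
typically the chloroplast markers *rbcL* (R), *matK* (M) and a spacer such
as *trnS*-*trnG* (T), plus the nuclear ITS region (I). A marker set is
useful when it shows a *barcoding gap*: divergence between species clearly
exceeds divergence within them. `barcodegap` quantifies that, per marker
and per combination, with the two standard criteria used in barcoding
studies of groups like the maples (Aceraceae), where 2–5 individuals are
sampled per species:

* **Gap criterion (PWG-distance).** For each species with distances
  `d(i, j) = P + Q` (uncorrected p-distance) or the Kimura 2-parameter
  correction `d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)` (transitions `P`,
  transversions `Q`, pairwise deletion of gap/ambiguous sites), the species
  passes iff `min d_inter > max d_intra` (strict).
* **Tree criterion.** Build the neighbor-joining tree from K2P distances,
  assess edges with a nonparametric bootstrap over alignment columns
  (1000 replicates by default); a species passes iff its individuals are
  monophyletic (one side of an edge's bipartition of the unrooted tree)
  with support strictly above 0.5.

The **discrimination rate** of a marker set is the percentage of species
passing a criterion (singletons excluded by default). Multi-locus units
are strict-intersection concatenations of the per-marker alignments.

A seeded synthetic-data generator (Yule species tree, within-species
stars, K2P sequence evolution on a marker rate ladder, shared indel
spans) produces complete datasets with known ground truth so the whole
pipeline can be exercised and calibrated offline. See
[docs/methods.md](docs/methods.md) for the model details and limitations.

## Worked example

Simulate the default 21-species, four-marker study and evaluate two of the
classical combinations:

```python
from barcodegap.simulate import SimulationConfig, simulate_dataset
from barcodegap.pipeline import EvaluationConfig, run_evaluation

dataset = simulate_dataset(SimulationConfig(seed=1), outdir="demo")
cfg = EvaluationConfig(
    marker_files={name: f"demo/{name}.fasta" for name in dataset.matrices},
    metadata_file="demo/metadata.tsv",
    combinations=[["trnS-trnG", "ITS"], ["rbcL", "matK", "trnS-trnG", "ITS"]],
    bootstrap_replicates=200,
    seed=1,
)
report = run_evaluation(cfg)
print(report.summary_frame().to_string(index=False))
```

prints (abridged to the core columns):

```
 region  n_samples  n_species  aligned_length  n_snps  pct_snp  n_indels  mean_inter  mean_intra  rate_pwg  rate_nj
      R         69         21             497      17     3.42         0      0.0041      0.0004     38.10    38.10
      M         69         21             636      31     4.87         1      0.0054      0.0003     66.67    71.43
      T         69         21             366      62    16.94        44      0.0208      0.0016     66.67    66.67
      I         69         21             346      82    23.70        21      0.0403      0.0014    100.00    90.48
    T+I         69         21             712     144    20.22        65      0.0303      0.0015    100.00    90.48
R+M+T+I         69         21            1845     192    10.41        66      0.0144      0.0008    100.00   100.00
```

Reading the table: each row is one evaluation unit (marker or
combination). `pct_snp` is the percentage of variable alignment columns,
`n_indels` the number of distinct gap events, `mean_inter`/`mean_intra`
the mean K2P divergence between/within species, and the two rates are the
percentage of species discriminated under the gap and tree criteria. The
slow coding marker (R) resolves few species; the fast nuclear spacer (I)
and the combinations containing it resolve most or all — the pattern
these pipelines are designed to expose.

The same analysis runs from the shell:

```sh
barcodegap simulate --out demo --seed 1
barcodegap run --config eval.yaml          # paths, combinations, knobs
barcodegap stats --alignment demo/ITS.fasta
barcodegap pwg  --alignment demo/ITS.fasta --metadata demo/metadata.tsv
barcodegap tree --alignment demo/ITS.fasta --metadata demo/metadata.tsv \
                -B 1000 --out ITS.nwk
```

`run` writes a `summary.tsv` (the table above), per-unit decision TSVs,
gap-histogram TSVs, newick trees with bootstrap supports, and a JSON run
log with the config, seed and dropped-pair tallies.

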
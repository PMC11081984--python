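# lcqspatial

Spatial hotspot statistics for immunohistochemistry-derived cell-centroid
patterns, built around the questions raised by marker expression in glandular
tissue: are marker-positive nuclei (for example nuclear pSTAT3 in the
periparturient mammary gland) clustered beyond chance, are whole alveoli
"committed" to high or low positivity, and do positive alveoli sit next to
other positive alveoli within a lobule?

The package is aimed at quantitative histopathology: it consumes the
centroid tables exported by pixel-classification tools (Ilastik /
CellProfiler style), plus optional binary masks of the ductal/alveolar
lumina — void regions where cells cannot occur — and ships a seeded synthetic
mammary-tissue generator so every analysis can be validated against known
ground truth.

## The statistic

For each cell *i* the **local colocation quotient** (LCQ) compares the
kernel-weighted local fraction of marker-positive nuclei with the global
fraction:

```
LCQ(i) = ( n_B(i) / n_A(i) ) / ( (N_B − 1) / (N_A − 1) )
```

* `N_A`, `N_B` — global counts of all nuclei and positive nuclei;
* `n_A(i)`, `n_B(i)` — Gaussian-kernel-weighted counts around cell *i*
  (self excluded), `w_ij = exp(−d_ij² / 2h_i²)`;
* `h_i` — adaptive bandwidth: the distance from cell *i* to its 10th
  nearest neighbour, so the "local area" tracks local cell density.

`LCQ > 1` means local enrichment of positive cells.  Significance comes from
random-labelling permutations (positive labels redistributed over the fixed
positions), with add-one p-values and Benjamini–Hochberg FDR across cells; a
cell is a hotspot call when `q ≤ α` and `LCQ > 1`.  Shed cells inside lumina
participate fully, so positive events in shed material remain detectable;
the void mask affects only simulation and rendering.

Around the hotspot statistic the package implements the alveolus-level
analyses: a 4-grade positivity scheme (grade 1 ≤ 25% positive luminal
epithelial cells, grade 2 26–50%, grade 3 51–75%, grade 4 > 75%), stratified
random sampling of positive/negative seed alveoli, percent-positive
immediately-adjacent alveoli within the same lobule (two-sided Mann–Whitney
between strata), and the same rank comparison applied to lumen dimensions,
which is an expected null when expression is unrelated to alveolar size.

## Worked example

```python
import lcqspatial as L

cfg = L.SimConfig(seed=1)                      # one synthetic gland
pattern, alveoli, adjacency, mask = L.simulate_tissue(cfg)

bw  = L.knn_bandwidths(pattern, k=10)
res = L.permutation_test(pattern, bw, n_perm=999, seed=42)

grades = L.grade_alveoli(pattern, alveoli)
dist   = L.grade_distribution(grades)
```

With the default study conditions this prints:

```
cells: 9860  positive: 1980  alveoli: 300  adjacency edges: 801
significant hotspot cells: 2506 (25.4%)
grade histogram (1-4): [207, 0, 2, 91]  extremity fraction: 0.993
% positive neighbours (7 glands pooled): positive seeds 78.6, negative seeds 65.8, p = 2.72e-07
lumen dimension null: major p = 0.01, minor p = 0.03
```

Reading the numbers: a quarter of all nuclei sit in statistically
significant hotspots (the planted committed lobules); the grade histogram is
strongly bimodal — almost every alveolus is either grade 1 or grade 4
(extremity fraction 0.993); and pooling 25 seed alveoli per stratum from
each of 7 simulated glands, positive-seed alveoli have markedly more
positive neighbours than negative-seed alveoli.  The lumen-dimension
comparison is a true null that rejects in ≈5% of glands at α = 0.05; this
particular example gland happens to be one of those 5% — across 100
replicate glands the suite verifies the nominal rate.

The same pipeline is available from the shell:

```sh
lcq simulate --seed 1 --out gland/
lcq run --cells gland/cells.csv --mask gland/mask.png --seed 42 --out lcq_out/
lcq grade --cells gland/cells.csv --alveoli gland/alveoli.csv --out grades/
lcq report --config run.yaml --out report/        # full pipeline, one config
```

Outputs are plain CSV/YAML/JSON plus a PNG hotspot overlay; every output
directory contains the fully resolved config and seeds that produced it, and
re-running from that config reproduces the outputs byte-for-byte.

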
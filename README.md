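# msntx

Morphometric-similarity-network (MSN) subtyping and imaging-transcriptomics
toolkit, exercised end-to-end on a synthetic cohort generator.

The pipeline goes from per-subject regional morphometric features (surface
area, cortical thickness, gray matter volume, Gaussian and mean curvature)
to:

1. **MSN construction** (`msntx.msn`) — per-subject region x region Pearson
   similarity of z-normalized feature vectors, without thresholding, plus
   regional "strength" maps (mean off-diagonal correlation) and Yeo-7 /
   von Economo network aggregation.
2. **Subtyping** (`msntx.subtyping`) — HYDRA-style semi-supervised polytope
   clustering: K weighted linear max-margin faces separating patients from
   controls, alternating hyperplane estimation and cluster assignment, with
   consensus over seeded restarts, an adjusted-Rand-index implementation,
   and tenfold cross-validated stability selection of the cluster count.
3. **Case-control statistics** (`msntx.group_stats`) — per-region OLS of
   strength on group + age + sex + TIV with two-sided t tests and
   Bonferroni correction, global strength tests, quadrant (decoupling /
   dedifferentiation / hypercoupling / hyperdifferentiation) fractions,
   quadratic age trajectories, symptom Spearman correlations, and
   demographics tables (Mann-Whitney U, chi-square).
4. **Expression preprocessing** (`msntx.expression`) — probe background
   filtering, probe-to-gene collapse by inter-probe homogeneity, sample to
   region assignment within 2 mm of the region boundary, and
   scaled-robust-sigmoid normalization to a left-hemisphere region x gene
   matrix.
5. **Imaging transcriptomics** (`msntx.transcriptomics`) — closed-form PLS1
   of expression against t-maps, spin (spherical rotation) and shuffle
   permutation tests, region-bootstrap gene Z scores with |Z| > 5 gene
   lists, ISH gene screening, cross-disorder DGE weight correlations, and
   Benjamini-Hochberg FDR.
6. **Cell types** (`msntx.celltypes`) — ssGSEA rank-weighted running-sum
   scores of marker sets per region and permutation tests for gene-list /
   marker-set overlaps.
7. **Synthetic data** (`msntx.synthetic`) — deterministic generators for
   spherical parcellations, cohorts with planted subtype effects and
   covariate structure, spatially autocorrelated expression with planted
   gradient genes, marker sets, and DGE tables, together with the planted
   ground truth for recovery tests.

## CLI

```bash
msntx simulate --seed 1 --out sim/                 # synthetic cohort
msntx msn --features sim/features.tsv --parcellation sim/parcellation.tsv --out msn/
msntx subtype --strengths msn/strengths.tsv --meta sim/meta.tsv \
      --kmin 2 --kmax 10 --consensus 5 --folds 10 --seed 1 --out subtypes/
msntx stats --strengths msn/strengths.tsv --meta sim/meta.tsv \
      --contrast patient-vs-control --out tmap.tsv
msntx pls --expr expr.tsv --tmap tmap.tsv --parcellation sim/parcellation.tsv \
      --n-perm 10000 --n-boot 10000 --seed 1 --out pls/
msntx cells --expr expr.tsv --sets cells.gmt --lists pls/pls1_lists.gmt \
      --seed 1 --out cells/
```

All file formats are plain text: tidy TSV for features and strengths, TSV
tables for metadata/parcellation/t-maps, GMT for gene sets.

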
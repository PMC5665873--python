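# exfoliomics

Analysis toolkit for comparing stool exfoliated-cell ("exfoliome") and
intestinal mucosal transcriptomes from gene-by-sample count matrices.

The package implements, as a reusable and fully tested pipeline:

- **Synthetic data** (`exfoliomics.simulate`) — a coupled three-source
  negative-binomial count simulator (small intestine, colon, exfoliome)
  with realistic per-source library sizes and dispersions, an injected
  treatment effect shared by a configurable subset of sources,
  housekeeping/marker gene annotations and full ground truth.
- **Preprocessing** (`exfoliomics.preprocess`) — low-abundance filtering
  (gene removed when detected in ≤ 4 samples or ≤ 50 reads total),
  upper-quartile normalization, (log-)CPM, housekeeping-gene diagnostics,
  cross-source Spearman screening.
- **Differential expression** (`exfoliomics.diffexpr`) — common
  negative-binomial dispersion by Cox–Reid adjusted profile likelihood,
  BCV, exact conditional two-group test with BH-FDR, MA tables and
  gene-set intersections.
- **Ordination** (`exfoliomics.ordination`) — Bray–Curtis dissimilarity,
  ANOSIM (permutation or exact enumeration), non-metric MDS (Kruskal
  stress-1 by majorization) and leading-logFC metric MDS.
- **Sparse CCA** (`exfoliomics.sparse_cca`) — diagonal-covariance sparse
  canonical correlation analysis: alternating soft-thresholded updates
  with a binary search on the L1 constraint, deflation for later
  components and leave-one-out CV tuning of the penalty pair.
- **Feature ranking** (`exfoliomics.lda`) — single-gene linear
  discriminant classification scored by closed-form bolstered
  resubstitution error.
- **Concordance** (`exfoliomics.concordance`) — marker-panel presence
  scoring (≥ 2 detected markers per category) and generic statistics over
  user-supplied pathway/regulator occupancy tables (proportions,
  two-proportion z, McNemar, Z-score correlation).

## Command line

Everything is reachable through one entry point:

```sh
# generate a self-contained synthetic dataset
exfoliomics simulate --out-dir data --n-genes 2000 --seed 1

# run the full chained pipeline (filter → normalize → dispersion/BCV →
# ordination/ANOSIM → DE → Venn/MA → sparse CCA → LDA ranking → markers)
exfoliomics run --input-dir data --output-dir results --seed 1
```

Individual stages are exposed as subcommands (`filter`, `normalize`,
`cpm`, `hkdiag`, `dispersion`, `de`, `venn`, `ma`, `ordinate`, `anosim`,
`cca`, `lda-rank`, `markers`, `concordance`); see `exfoliomics <cmd>
--help`.  `run` accepts a YAML/JSON config file whose keys mirror the
flags; CLI flags override the file.  Every written table gets a
`.prov.json` sidecar recording input checksums, parameters, seed and
package version, and reruns with the same config and seed are
byte-identical.

Count matrices travel as TSV (genes in rows) or MatrixMarket with
plain-text row/column index files; metadata is a TSV with columns
`sample_id`, `source`, `group`, `subject`.

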
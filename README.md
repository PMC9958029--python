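# hnscc-stepwise

A tested, reusable pipeline for single-cell analyses of stepwise tumor
progression across four tissue states (normal → premalignant → primary
carcinoma → nodal metastasis):

- **Copy-number inference from expression** — per-cell log2 tracks against an
  immune-cell reference, circular binary segmentation with a permutation
  split test, gain/loss calls, aberrant-gene burden, and recurrent-region
  calling per tissue type, with gene-set hygiene (sex chromosomes, IG/TR
  biotypes, GO-enriched 1 Mb co-functional clusters excluded).
- **Carcinoma-in-situ detection** — premalignant epithelial cells labeled by
  similarity (correlation + burden) to the mean malignant track; aberrant
  immune cells reassigned as undetermined.
- **Permutation differential programs** — Welch-t permutation tests (exact
  enumeration when feasible), rank-sum cluster markers, copy-number-dependent
  gene calls, and stepwise gene detection along the progression.
- **Ligand-receptor interdependence** — obligate-paracrine pairs: stepwise
  ligand detection in fibroblasts, receptor detection in malignant cells,
  ligand absence in malignant cells; per-patient coupling with an autocrine
  control.
- **Deconvolution + survival** — union-of-markers signatures, NNLS bulk
  proportions, nearest-template prediction with a gene-permutation null,
  percentile stratification, and Kaplan-Meier / log-rank testing with an
  O/E hazard-ratio estimate.
- **Synthetic cohorts** — a generator planting known ground truth (clonal CNA
  segments, an in-situ subclone, stepwise ligand programs, bulk mixtures,
  proportion-linked hazards) so every stage is quantitatively testable
  offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the quantitative acceptance criteria
(calibration, oracle-equality, and ground-truth recovery bounds); it takes a
few minutes because it profiles a full synthetic cohort.

## CLI

```bash
hnscc-stepwise simulate --seed 1 --out cohort/            # synthetic cohort (MTX + TSV)
hnscc-stepwise cna     --data cohort/ --tissue CA --out out/cna
hnscc-stepwise cis     --data cohort/ --out out/cis
hnscc-stepwise de      --data cohort/ --cell-type fibroblast --out out/de
hnscc-stepwise lr      --data cohort/ --out out/lr
hnscc-stepwise deconv  --data cohort/ --bulk bulk.tsv --out out/deconv
hnscc-stepwise survive --proportions props.tsv --survival surv.tsv --focal CC1 --out out/surv
```

Every stage accepts `--config config.yaml`; the YAML mirrors
`hnscc_stepwise.config.PipelineConfig` field-for-field (thresholds, window
sizes, permutation counts, seed).

## Data formats

Expression matrices are MatrixMarket (`matrix.mtx`) or dense TSV, with
`cells.tsv` / `genes.tsv` metadata (cell: patient, tissue type NL/LP/CA/LN,
HPV status, cell type; gene: chromosome, 1-based inclusive coordinates,
biotype, semicolon-separated GO terms). Survival tables and ligand-receptor
lists are TSV. All outputs are TSV with headers and round-trip losslessly.
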
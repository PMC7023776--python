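# emtmeth

Tools for studying DNA-methylation-driven epithelial-to-mesenchymal
transition (EMT) and therapy resistance, from cell-line arrays to
longitudinal liquid biopsies:

- **EMT scoring from expression** — CPM log2 fold changes, delta-delta-Ct
  with data-driven housekeeper selection, and an
  epithelial-versus-mesenchymal Mann-Whitney comparison with a "full EMT"
  call.
- **Differential methylation** — Δβ computation, hyper/hypo CpG calling at
  the 0.3/0.7 thresholds, promoter-level EMT methylation scoring, quadrant
  enrichment against expression changes, and a shared-overlap binomial test
  between resistant models.
- **TET-activity inference** — TAB-based 5mC/5hmC separation and the
  5mC-decile analysis contrasting the 5hmC of variably versus stably
  methylated CpGs.
- **Capture-panel design** — selection of CpGs unmethylated in healthy
  blood (mean β < 0.03) and merge-and-pad construction of capture regions.
- **cfDNA deconvolution** — ctDNA fraction estimation by through-origin
  regression of measured methylation on a tumor reference, tumor-methylome
  reconstruction, marker exclusion against healthy-control cfDNA,
  longitudinal EMT trajectories, and tissue–liquid rank correlation.
- **Synthetic data** — seeded generators for every input (beta matrices,
  TAB arrays, expression counts, reference cohorts, Bismark coverage
  files) with known ground truth for recovery testing.

A 50-gene EMT signature (16 epithelial, 34 mesenchymal) and the 13-marker
cfDNA exclusion list ship as package data.

## Command line

Every stage is a standalone subcommand; `run-all` simulates a fixture and
chains them:

```sh
emtmeth run-all --seed 7 --out runs/demo
emtmeth simulate --seed 7 --out fixture/
emtmeth design-panel --blood fixture/blood_reference.tsv --threshold 0.03 --out panel.bed
emtmeth score-emt-expression --counts fixture/expression.tsv --signature fixture/signature.tsv
emtmeth diffmeth --beta fixture/standard.tsv --out calls.tsv
emtmeth tet-bins --standard fixture/standard.tsv --tab fixture/tab.tsv --out tet.tsv
emtmeth deconv --coverage-dir fixture/coverage --sheet fixture/sample_sheet.tsv \
    --tumor fixture/tumor_reference.tsv --targets panel.targets.tsv --out deconv.tsv
emtmeth trajectory --coverage-dir fixture/coverage --sheet fixture/sample_sheet.tsv \
    --tumor fixture/tumor_reference.tsv --genes fixture/genes.tsv \
    --signature fixture/signature.tsv --exclude fixture/excluded_markers.txt \
    --out trajectory.tsv
```

All inputs are plain text: tab-separated beta matrices (id/chrom/pos +
one column per sample), 6-column Bismark coverage files, BED for capture
regions, and tab-separated signature / annotation / sample-sheet tables.
Outputs carry a header comment with the seed and a parameter hash; the
same seed reproduces artifact directories byte for byte.

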
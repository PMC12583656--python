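# Published supplementary matrices (not distributed)

The acceptance test
`tests/test_acceptance.py::test_published_matrix_cluster_statistics`
evaluates the cluster permutation statistics on the study's published
35×35 matrices.  Those supplementary datasets are not redistributable with
this repository; to run the check, download them once and save here as
tab-separated labelled square matrices (first row and first column are the
35 protein names, e.g. FolA, FolK, GlyA, …; missing cells coded `NA`):

- `dataset_ev1.tsv` — symmetric mean-fluorescence-intensity (MFI) matrix
  (per-pair maximum over the two fusion orientations)
- `dataset_ev3.tsv` — TM-score structural-similarity matrix

`metabolon validate <file>` checks the format.  Without these files the
test fails with a message pointing here; every other test is
self-contained.
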
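# Packaged fixtures

All fixtures are transcriptions of the printed tables of the published
aortic-stenosis (AS) biomarker prioritization study; the study deposited no
machine-readable data, so these TSV/YAML files are the only inputs that can
be packaged.

- `candidates_table1.tsv` — the 126 candidate proteins (UniProt accession,
  protein name, and the citation tags of the proteomics studies they came
  from), sorted by accession.
- `score_matrix_table5.tsv` — the published strong-relationship sub-matrix:
  the 22 proteins strongly related to at least three disease processes, one
  row per (protein, process) pair with the printed relationship score
  (0–100) and the printed effector flag. Rows are grouped by protein in the
  published rank order (decreasing best score). This is a *sparse* matrix:
  only strong-band rows were printed.
- `disease_map_as.yaml` — the eight pathophysiological processes ("motives")
  with their causal level (causative / symptomatic / both), plus the
  disease-in-general pseudo-process. Effector sets contain only the
  accessions recoverable from the printed effector flags of
  `score_matrix_table5.tsv`; the study's full 168-protein effector list was
  in a non-deposited appendix. For scoring experiments at realistic scale
  use the synthetic-study generator instead.
- `strong_counts_table4.tsv` — the published per-process counts of
  strongly-related proteins, cross-tabulated by score band and effector
  status ("-" printed cells transcribed as 0). Used only to verify report
  arithmetic; the underlying full score matrix is not reproducible.
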
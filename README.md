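# plvnet

Band-resolved phase-locking-value (PLV) brain networks from multichannel
EEG-style signals, with everything needed to exercise the full analysis
chain on synthetic data:

1. **synthdata** — labeled synthetic cohorts (two groups x pre/stimulus/post
   conditions) with controlled band-specific phase coupling. Channel phases
   are convex mixtures of a shared narrowband driver (weight kappa) and
   independent phase tracks, so the expected pairwise PLV rises
   monotonically with the coupling strength and the generator/estimator
   loop can be closed quantitatively.
2. **preprocess** — channel selection (19-channel 10–20 montage by
   default), common average reference, zero-phase FIR bandpass
   (0.1–30 Hz broadband plus canonical delta/theta/alpha/beta bands),
   condition segmentation.
3. **connectivity** — instantaneous phase via the Hilbert analytic signal;
   PLV adjacency matrices per (subject, condition, band).
4. **graphnet** — binarization at a fraction (default 80%) of the maximum
   off-diagonal PLV; mean clustering coefficient, characteristic path
   length, node degrees, all with audit-friendly intermediates.
5. **analysis** — per-subject feature tables, two-sided permutation tests
   (label permutation / sign flip, Welch-t statistic, exact enumeration at
   small n), and 10-fold cross-validated SVM/DT/KNN/RF classification with
   leakage-free in-fold standardization.
6. **cli / pipeline** — composable subcommands and a deterministic
   end-to-end runner with a checksummed manifest.

## CLI

Full pipeline with built-in synthetic defaults (8 subjects per group,
1 min pre / 4 min stimulus / 1 min post at 500 Hz):

```sh
plvnet run --out results/run1 --seed 1
```

Stage by stage (each step consumes the previous step's on-disk output):

```sh
plvnet simulate   --n-per-group 2 --seed 7 --out raw/
plvnet preprocess --in raw/ --out clean/
plvnet connect    --in clean/ --out matrices/
plvnet metrics    --in matrices/ --out metrics.tsv --fraction 0.8
plvnet classify   --in metrics.tsv --out report.json --seed 7
```

Recordings are exchanged as plain CSV matrices (one column per channel,
one-line label header) plus a JSON cohort manifest; connectivity matrices
as labelled CSV and a long-format TSV; metrics as tidy TSV; classifier
results as JSON and a compact TSV table. A full `plvnet run` additionally
writes `comparisons.tsv` (permutation-test contrasts) and
`run_manifest.json` with SHA-256 checksums — two runs from the same master
seed produce byte-identical artifacts.

Configs round-trip through YAML or JSON (`PipelineConfig.save/load`);
`--seed` / `--n-per-group` override config values.

## Notes

- The dedicated acceptance tests live in `tests/test_acceptance.py`:
  analytic PLV anchors, brute-force oracle equivalence for all graph
  metrics (112 connected 6-node graphs plus 500 random 19-node graphs),
  estimator closure over a coupling-strength grid, permutation-test type-I
  calibration, a cross-validated classification analog on the default
  synthetic cohort, and byte-level determinism of the pipeline.
- EDF input is not supported in this build; use the CSV interchange format
  (an EDF reader can be slotted in at `synthdata.read_cohort`).
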
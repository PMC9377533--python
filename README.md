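# fcgraph

Longitudinal functional-connectivity graph analysis for node-level brain
time series. The pipeline goes from per-session T×N node signals to binary
graphs and back out to brain–behaviour statistics:

1. **Scrubbing check** — subjects with more than 30 censored volumes are
   excluded (strict inequality).
2. **Prewhitening** — per-node AR(p) residuals, order chosen by AIC.
3. **Pearson correlation** — N×N connectivity matrix per session.
4. **Proportional thresholding** — keep the strongest 20% of connections
   as binary undirected edges (signed ranking by default, absolute-value
   mode available; deterministic lexicographic tie-breaking).
5. **Graph metrics** — degree, clustering coefficient, characteristic path
   length and betweenness centrality on the binary graph (one shared BFS /
   Brandes pass; betweenness normalised to [0, 1]).
6. **Relative change** — ΔM = (M2 − M1)/M1 per node between sessions, with
   a display filter keeping nodes whose |ΔM| exceeds half the mean |ΔM|.
7. **Anatomical attribution** — nearest-coordinate assignment of nodes to
   named regions (packaged coordinate table), hemisphere flipping for
   left-lesion subjects, and per-region increase/decrease summaries split
   into ipsilesional (x > 0) / contralesional (x < 0) hemispheres.
8. **Brain–behaviour correlation** — ROI-averaged betweenness change
   (primary sensorimotor / supplementary motor / premotor, per hemisphere)
   against upper-extremity motor-score change, Pearson r with exact-t
   two-sided p per panel (optional Spearman and Holm correction).

A first-class synthetic-cohort generator (`fcgraph.synth`) stands in for
real data: modular latent-factor covariance with AR(1) temporal structure,
two sessions per subject, a session-2 "hub shift" that turns chosen target
nodes into inter-community bridges, and a clinical table whose simulated
motor recovery is coupled to the per-subject shift magnitude. Everything is
deterministic given one master seed.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including two
Monte-Carlo checks (type-I-error calibration of the panel test under a null
simulator, and power/ordering checks under a strong planted effect) that
run the full pipeline a few hundred times at reduced size; the whole suite
takes a few minutes on one CPU.

## CLI

```bash
fcgraph simulate --config config.yaml --seed 1 --out cohort/
fcgraph run --cohort cohort/ --out results/
fcgraph report --results results/
```

`simulate` writes one TSV per subject-session plus `nodes.csv`,
`clinical.csv`, `scrub.csv`, `ground_truth.csv` and a checksum
`manifest.json`. `run` executes the full pipeline (group-average path and
individual-correlation path) and persists every stage: per-subject edge
lists and metric tables, per-group ΔM maps and region summaries,
`correlations.csv` (one row per ROI × hemisphere), scatter data and a
machine-readable `run_log.json`. Stage-level commands (`connect`,
`metrics`, `delta`, `correlate`) operate on single files for ad-hoc use.

Config is a single YAML document with `simulation:` and `pipeline:`
sections; CLI flags override file values. Identical config + seed yields a
byte-identical output tree.

## Layout

```
src/fcgraph/
  synth.py          synthetic cohorts, toy graphs, serialization
  atlas.py          node tables, hemisphere flip, region attribution
  connectivity.py   scrubbing, prewhitening, Pearson, thresholding
  metrics.py        degree / clustering / path length / betweenness
  longitudinal.py   ΔM, display filter, region aggregation
  clinical.py       group assignment, score deltas, panel correlations
  pipeline.py       orchestration + results-tree writer
  cli.py            click entry points
  data/             packaged region-coordinate table and default ROI spec
```
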
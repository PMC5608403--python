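# cyclemap

Single-cell analysis of the proliferation–quiescence decision from
time-lapse microscopy plus endpoint immunofluorescence (IF).

Cultured mammalian cell populations are heterogeneous even under optimal
growth conditions: after mitosis some cells immediately recommit to the
cell cycle, others enter a spontaneous quiescent (G0) state, and some of
those later re-enter the cycle.  A CDK2 activity sensor — a fluorescent
substrate whose cytoplasmic:nuclear ratio tracks CDK2 kinase activity —
distinguishes these states in live cells.  `cyclemap` implements the
computational side of such experiments:

- **Segmentation** of H2B/Hoechst-labelled nuclei: log-transform +
  Laplacian-of-Gaussian detection, with a *deflection bridging* algorithm
  that splits touching nuclei along perimeter concavities.
- **Tracking** by nearest-future-neighbour linking screened for
  conservation of total H2B fluorescence ("conservation of mass"), with
  mass-based merge/split detection.  A mitosis is called at anaphase when
  the two nearest future neighbours each carry 45–55% of the mother's
  total H2B signal.
- **Quantification**: local-median and global-mode background models and
  CDK2 activity as the ratio of cytoplasmic (top-50% perinuclear ring
  mean) to nuclear mean sensor fluorescence.
- **Fate classification**: CDK2^inc (activity ≥ 0.5 at every
  post-anaphase frame), CDK2^low (< 0.5 throughout), CDK2^emerge (low for
  ≥ 3 h, then a confirmed rise), plus prolonged-quiescent and
  nondividing-emerge classes for cells with no mitosis in the movie.
- **Computational synchronization**: traces aligned to the last anaphase
  or to the R-point (the time CDK2 activity first begins to rise, found
  by maximizing a linear score in time-since-mitosis, activity, and
  windowed slope).
- **Jitter registration** between the last live frame and the fixed-cell
  IF images (exhaustive integer-shift search minimizing a mean absolute
  difference score), so each cell's IF staining is matched to its
  history.
- **Snapshot phase gating** from DNA content, EdU, phospho-Rb and pHH3
  into G0 / G1 / early S / S / late S / G2 / M.
- **Protein-dynamics maps**: per-fate moving averages of endpoint IF
  versus time-since-anaphase, joint min–max normalization of
  proliferating vs quiescent curves, and Group 1 / Group 2 assignment
  (proteins "off" in quiescence vs changing during quiescence).
- A **synthetic data generator** (`cyclemap.simdata`) producing movies,
  endpoint IF and snapshot populations with full ground truth, used by
  the test suite to validate the whole chain end-to-end.

## Worked example

Simulate a 200-cell asynchronous cohort, run the full movie pipeline, and
look at the recovered population structure:

```python
from cyclemap import pipeline, simdata

cfg = simdata.SimConfig(n_cells=200, seed=7)
cohort = simdata.simulate_cohort(cfg)
result = pipeline.analyze_cohort(pipeline.PipelineConfig(sim=cfg), cohort)
for key in ("pct_divided", "pct_CDK2inc", "pct_CDK2low", "pct_CDK2emerge",
            "pct_prolonged_quiescent", "pct_nondividing_emerge"):
    print(f"{key:28s} {result.fractions[key]:5.1f}")
```

prints

```
pct_divided                   95.5
pct_CDK2inc                   76.0
pct_CDK2low                   10.0
pct_CDK2emerge                 9.5
pct_prolonged_quiescent        3.0
pct_nondividing_emerge         1.5
```

meaning: 95.5% of the 200 tracked lineages showed a detected anaphase
within the 24 h movie; 76.0% of the population entered the CDK2^inc
(cycle-committed) state after mitosis, 10.0% stayed CDK2^low
(spontaneously quiescent), 9.5% emerged from quiescence before the movie
ended, 3.0% never divided and stayed quiescent throughout, and 1.5%
built up CDK2 activity without a mitosis.  For this seed the generator's
ground truth is 96.0% divided / 76.5 / 10.0 / 9.5 / 2.5 / 1.5 — the
pipeline recovers the composition to within a lineage or two, through the
full imaging round-trip (rendering, segmentation, tracking, anaphase
detection, ring quantification, classification).

The same result object feeds the IF stages:

```python
est, true_shift, truth = pipeline.attach_endpoint_if(result, ["p21", "CyclinD1"])
curves = pipeline.build_dynamics(result, "CyclinD1")
```

A thin CLI mirrors the stages (`cyclemap simulate / segment / quantify /
track / register / classify / gate / map / run`); see `cyclemap --help`.

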
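# petite-dynamics

Quantitative analysis of mitochondrial genome (mtDNA) loss in growing
budding-yeast populations, and of genetic screens for dosage suppressors of
the mtDNA-depleted state.

Stress on the mitochondrial proteome destabilizes mtDNA: respiration-
competent ρ⁺ cells convert to respiration-deficient ρ⁰ cells, which grow
more slowly and form small ("petite") colonies. This package provides the
full analysis chain for studying that process with standard lab readouts —
plate-reader growth curves, colony-area plating assays, and pooled
barcode-sequencing screens — plus synthetic-data generators so every stage
is testable without any sequencing download.

## The model

A population holds ρ⁺ cells `P_wt(t)` and ρ⁰ cells `P_mut(t)`:

    dP_wt/dt  = (G_wt − r) · P_wt
    dP_mut/dt = G_mut · P_mut + r · P_wt

where `G_wt`, `G_mut` are exponential growth constants (per hour, base e)
and `r` is the per-cell mtDNA loss rate. The closed form is

    P_wt(t)  = P_wt(0) · e^{(G_wt − r) t}
    P_mut(t) = P_mut(0) · e^{G_mut t} + r P_wt(0) · (e^{(G_wt−r)t} − e^{G_mut t}) / (G_wt − r − G_mut)

(with the `t·e^{G_mut t}` degenerate form when `G_wt − r = G_mut`).
If `G_wt − r > G_mut` the mutant fraction converges to the equilibrium
`f* = r / (G_wt − G_mut)` and the population grows at the weighted average
`(1−f*)·G_wt + f*·G_mut`; otherwise the mutant fixes. Because conversion
changes a cell's state rather than removing it, the per-capita growth rate
is that weighted average at *every* time.

Around the model sit four analysis stages:

- **growth**: log-linear fitting of OD600 curves truncated to the linear
  range; Welch t comparisons; Pearson validation correlation.
- **petite**: petite calls from colony area (petite iff area < 1.5 mm²),
  threshold recalibration from respiration-labeled colonies, and loss-rate
  estimation `r̂` from time-resolved petite counts (weighted least squares
  against `f(t; r, f0)`, replicate-bootstrap CI).
- **screen**: exact-match demultiplexing of barcoded amplicon reads;
  conditional binomial exact test per gene on pooled, library-size-rescaled
  counts; signed rank metric `sign(enrichment) · (−log10 p)`;
  Benjamini–Hochberg FDR; hit selection.
- **synthetic**: generators for every input, including an exact
  event-driven (Gillespie) counterpart of the deterministic model.

## Worked example

```python
from petite_dynamics import TwoStateParams, estimate_loss_rate
from petite_dynamics import synthetic as syn

params = TwoStateParams(g_wt=0.4, g_mut=0.4, r=0.15)   # true r = 0.15/h
series = syn.generate_petite_time_series(
    params, sampling_times=[0, 3, 6, 9], colonies_per_plate=150,
    n_replicates=8, baseline_fraction=0.05, seed=42)
est = estimate_loss_rate(series, g_wt=0.4, g_mut=0.4, n_boot=1000, seed=7)
print(est.r_hat, est.ci_lower, est.ci_upper)
```

prints (as run by `examples/02_loss_rate_measurement.py`):

```
estimated loss rate r_hat = 0.150 /h
estimated baseline  f0    = 0.045
90% bootstrap CI       = (0.145, 0.155)
```

i.e. from 32 plates of ~150 colonies the loss rate is recovered to well
within sampling error, and the fitted baseline matches the 5% petite
fraction present before selection was relaxed. The petite fraction itself
rises from ~4% to ~74% over 9 h under these parameters.

The `examples/` directory has one short script per capability (model and
regimes, loss-rate measurement, growth-rate fitting and comparison, full
barcode screen); each prints its numbers with a line of interpretation.
A thin CLI mirrors the file-based steps:
`petite-dynamics <simulate|fit-growth|call-petite|calibrate-threshold|loss-rate|demux|screen-test|select-hits|run>`.

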
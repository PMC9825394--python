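# ipitune

Quantitative analysis of inter-pulse-interval (IPI) tuning in the early
auditory circuit of *Drosophila*, comparing *D. melanogaster* and
*D. simulans* females.

Male flies court with "pulse songs" — trains of brief sound pulses whose
inter-pulse interval is species-typical (~35 ms in *D. melanogaster*, ~55 ms
in *D. simulans*) — and females copulate sooner when they hear songs with
conspecific intervals.  The secondary auditory neurons (AMMC-B1) respond to
pulse songs with band-pass IPI selectivity.  This package implements the
full analysis chain that quantifies that selectivity and its interspecific
divergence, for both the imaging and the behavioural arm:

* **Calcium-trace processing** — ROI-mean GCaMP fluorescence at 10 frames/s
  is smoothed (3-frame moving average), photobleaching is removed by a
  linear fit over quiet windows, ΔF/F = (F − F_base)/F_base is computed
  against the second before stimulus onset, and per-stimulus peak responses
  are normalized by their sum over the ten tested IPIs
  (15, 25, …, 105 ms) to give each individual's tuning curve.
* **Tuning model** — the curve is fitted with a difference of exponentials,

      y(x) = a·e^(−x/τ_b) − c·e^(−x/τ_d),

  a slow excitatory decay minus a fast inhibitory decay, whose interior
  maximum (the *peak IPI*) is available in closed form:

      x* = [τ_b·τ_d/(τ_b − τ_d)] · ln(c·τ_b/(a·τ_d)).

  Per-individual parameters are estimated by a hierarchical Bayesian model
  (log-normal between-individual pooling, Gaussian observation noise)
  sampled by a blocked Metropolis-within-Gibbs MCMC written for this model,
  with ArviZ convergence diagnostics.  A deterministic log-scale
  least-squares fit serves as an independent oracle.
* **Group statistics** — exact Wilcoxon rank-sum tests (full enumeration of
  the null by the shift algorithm, two-sided p = 2·min tail),
  Bonferroni-corrected Welch t-tests on the 25-ms-referenced response
  drops, and a Gaussian linear model for the pure-tone frequency × species
  interaction.
* **Behavioural survival analysis** — cumulative copulation rates
  (1 − Kaplan–Meier), restricted mean time lost (RMTL; exact step
  integration, RMTL + RMST = τ), and Cox proportional-hazards
  species × IPI interaction hazard ratios against the 35-ms
  *melanogaster* reference within a 0–7 min proportionality window.
* **Synthetic data** — the raw recordings are not deposited, so a
  first-class generator reproduces the statistical structure the analysis
  assumes: log-normal individual parameters calibrated to the published
  per-individual estimates, GCaMP-like transients on a bleaching baseline,
  and exponential copulation times with administrative censoring.

The published per-individual parameter estimates (12 + 13 individuals plus
species averages) ship as a packaged CSV — they are the *input* to the
comparison statistics.

## Worked example

```python
>>> import ipitune as it
>>> row = it.reference_average("melanogaster")
>>> params = it.TuningParams(row.a, row.tau_b, row.c, row.tau_d)
>>> round(params.peak_ipi_ms, 4)
21.6406
>>> row_s = it.reference_average("simulans")
>>> round(it.analytic_peak((row_s.a, row_s.tau_b, row_s.c, row_s.tau_d)), 4)
25.0421
>>> mel = it.reference_individuals("melanogaster")
>>> sim = it.reference_individuals("simulans")
>>> res = it.exact_wilcoxon(mel.peak_ipi_ms, sim.peak_ipi_ms)
>>> f"{res.p_two_sided:.3g}"
'3.85e-07'
```

The closed-form peak of the *melanogaster* average fit sits at 21.64 ms and
the *simulans* average at 25.04 ms: both species' secondary auditory
neurons prefer ~25-ms intervals, but the *simulans* optimum is shifted
toward longer IPIs — the same direction as the behavioural preference
shift.  The exact rank-sum test on the 12 vs 13 individual peak IPIs
separates completely (U = 0), giving the smallest attainable two-sided
p-value 2/C(25,12) = 3.85×10⁻⁷.

## Analysis scripts

`analysis/01_simulate.py … 05_behavior.py` run the arms end to end on
synthetic data and write their tables under `results/` (each script's
docstring says what it computes; run them in order from the repository
root).  The same stages are available as a CLI:

```bash
ipitune all --seed 11 --out results/run1
```

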
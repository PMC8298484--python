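# circatemp

Data-driven profiling of circadian wrist skin-temperature rhythms in
free-living cohorts.

Wrist temperature follows a roughly 24-hour rhythm that peaks at night, and
how that rhythm is shaped — its level, its swing, its timing — carries
information about a person's sleep behaviour and circadian preference.
`circatemp` implements a complete analysis pipeline for minute-resolution
wrist-logger recordings of the kind produced by coin-sized thermochron
devices worn for about three days: per-subject cosinor rhythmometry,
clustering of whole temperature profiles, actigraphy-style sleep summaries
with a delayed-sleep-phase (DSP) rule, and bootstrap/FDR association
analyses between the three. It targets chronobiologists and sleep
epidemiologists who want a tested, seeded, end-to-end reference
implementation — and, because cohort temperature data are rarely shareable,
it ships a synthetic-cohort generator so every stage is exercisable without
any download.

## The model

Each subject's series is described by a single-component cosinor

$$Y(t) = M + A\cos\!\left(\frac{2\pi t}{\tau} + \phi\right) + e(t)$$

where $M$ (mesor) is the rhythm-adjusted mean in °C, $A$ the amplitude
(half the peak-to-trough extent), $\tau$ the period in hours, and $\phi$
the acrophase angle fixing the clock time of the peak. For fixed $\tau$ the
model is linear in $\beta = A\cos\phi$, $\gamma = -A\sin\phi$ and is fit by
least squares; $\tau$ is then profiled over [20, 30] h by a grid-plus-
golden-section search. The acrophase is recovered from $(\beta,\gamma)$ by
a full four-quadrant sign resolution so peak clock times are correct in
every quadrant.

Above the per-subject fits, whole 48-h profiles are reduced to their DC
term plus the first 24 discrete-Fourier harmonics and clustered with
Partitioning Around Medoids (PAM); the number of clusters is judged by
Silhouette, Dunn and Davies–Bouldin indices plus eigenvalue-based
RMSEA-like/eBIC-like dimension-fit indices, with t-SNE and
network-modularity stability diagnostics. Group differences are tested
with bias-corrected percentile bootstrap CIs, null-imposed bootstrap
omnibus tests, maximum-likelihood logistic models (odds ratios per SD),
and a single Benjamini–Hochberg FDR family across all omnibus tests.

## Worked example

```python
import numpy as np
import circatemp as ct

# one synthetic subject from the highest-mesor archetype, low noise
arch = ct.default_archetypes()[0]
rec = ct.generate_series(arch, ct.NoiseSpec(sigma=0.1), seed=1)
series = ct.harmonize_start(rec)        # 48 h from the first noon
fit = ct.estimate_period(series)        # cosinor with period search
print(f"mesor {fit.mesor:.2f} degC  amplitude {fit.amplitude:.2f} degC  "
      f"period {fit.period:.2f} h  peak {fit.acrophase_clock}")
```

```
mesor 34.42 degC  amplitude 1.05 degC  period 25.15 h  peak 05:04
```

The subject's realized parameters (jittered around the archetype's
mesor 34.29 °C, amplitude 1.02 °C, period 25.75 h) are recovered to within
a few thousandths of a degree; the reported peak is the first model peak
inside the analysis window — with a 25.2-h period the peak drifts more
than an hour later each day.

The full pipeline is one call (or `circatemp run` from a shell):

```python
manifest = ct.run_pipeline(ct.RunConfig(outdir="run", seed_simulate=11))
print(manifest["stages"]["cluster"])
```

which simulates the default three-cluster cohort (100/130/51 subjects),
preprocesses, fits, clusters, summarizes sleep and writes the association
report; the manifest records the cluster sizes and the agreement of the
partition with the generating labels.

### Command line

```bash
circatemp simulate --seed 11 --out cohort/
circatemp preprocess cohort/temperature.csv --span 0.3 --ncp 2
circatemp fit preprocessed/smoothed_matrix.csv --tau-min 20 --tau-max 30
circatemp cluster preprocessed/smoothed_matrix.csv --k-range 2 6 --seed 11
circatemp sleep cohort/sleep.csv --meq-csv cohort/meq.csv
circatemp run --out run/
```

Output schemas (one example row each):

| file | example row |
|---|---|
| `temperature.csv` | `S0000,2017-01-09 18:19:00,34.0625` |
| `sleep.csv` | `S0000,0,2020-01-10 00:05:00,2020-01-10 00:25:00,2020-01-10 08:20:00,52.1` |
| `meq.csv` | `S0000,2,3,1,4,5,2` |
| `cosinor_params.csv` | `S0000,34.29,1.02,25.75,-0.31,02:40,15:32,02:38,14:05,41.2` |
| `clusters.csv` | `S0000,1` |
| `validity.csv` | `3,0.57,0.32,0.59,0.08,-68.3,9.92` |
| `sleep_summary.csv` | `S0000,07:59,7.98,...,True,13` |

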
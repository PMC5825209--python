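# burstabc

Stochastic promoter-cycle simulation and likelihood-free inference for
live-cell nascent-transcription time traces.

`burstabc` is built for experiments in which a stem-loop reporter (e.g.
PP7/PCP) makes the transcription site of an endogenous gene visible as a
fluorescent focus, so that each cell yields a time series of
transcription-site intensity in single-RNA-equivalent units.  The package
answers the questions such data pose: what promoter architecture (how many
rate-limiting ON and OFF steps), which kinetic parameters (burst size,
ON/OFF times), which sources of cell-to-cell (extrinsic) variability, and —
across a stimulus titration — whether the stimulus modulates burst
frequency or burst size.

## The model

The promoter cycles irreversibly through `n_off` inactive and `n_on`
active states.  Each state `i` is left at constant rate, so with
`k_on = n_off / t_OFF` per OFF state and `k_off = n_on / t_ON` per ON
state the total OFF- and ON-times are Erlang distributed with means
`t_OFF` and `t_ON` (exponential for the classic two-state telegraph
model).  While ON, transcripts initiate as a Poisson process with rate
`k_init = b / t_ON`, giving `b` transcripts per ON passage on average.
State switching and initiation are simulated exactly (stochastic
simulation algorithm); elongation is deterministic: every transcript
contributes a trapezoidal unit signal that rises over ~2 min and
disappears at termination/release, 30 min after initiation at the
reference elongation speed.  The rendered trace is the superposition of
these profiles plus additive Gaussian measurement background.

Extrinsic noise enters by resampling selected parameters once per cell
from a truncated normal, `X ~ N(mu, (cv * mu)^2)`, shared between the two
alleles of the same cell.  Eight noise variants (0–7) select which of
`{k_elong, k_init, k_on, k_off}` are resampled; a model is written
`n_on-n_off-variant`, e.g. `1-1-5` for the two-state cycle with
initiation- and elongation-rate variability.

Inference is sequential Monte Carlo approximate Bayesian computation
(SMC ABC): a population of particles (model + parameters) is refined by
simulating each particle under the experimental protocol and scoring a
five-feature distance — global intensity histogram, population-mean
autocorrelation function, per-cell distributions of ACF half-life and
lag-1 ACF, and a kernel maximum-mean discrepancy between per-trace
summary vectors.  The weights are calibrated so two replicate simulations
of the same model sit at distance ~0.5, which doubles as the convergence
floor.  A multi-condition *global fit* shares all parameters across
conditions except one local parameter (`t_OFF` or `k_init`), which is how
burst-frequency modulation is separated from burst-size modulation.

## Worked example

```python
import numpy as np
from burstabc import (
    KineticParams, PromoterModelSpec, build_topology,
    simulate_population, add_measurement_noise, allele_output_correlation,
)

# two-state promoter, OFF 50 min, 10 RNAs per burst, extrinsic noise on
# initiation and elongation shared between sister alleles
params = KineticParams(t_on=0.6, t_off=50.0, burst_size=10.0,
                       cv_ext={"k_init": 0.35, "k_elong": 0.35})
model = PromoterModelSpec(build_topology("1-1-5"), params)

rng = np.random.default_rng(7)
ds = simulate_population(model, n_cells=45, alleles_per_cell=2, rng=rng)
ds = add_measurement_noise(ds, rng=rng)
corr = allele_output_correlation(ds, rng=rng)
print(f"sister-allele output PCC = {corr.pcc:.2f} "
      f"(bootstrap {corr.boot_mean:.2f} +/- {corr.boot_sd:.2f})")
```

```
sister-allele output PCC = 0.79 (bootstrap 0.76 +/- 0.10)
```

The shared per-cell draws of the initiation and elongation rates
correlate the total RNA output of the two alleles even though their
moment-to-moment bursting is independent.  A single 45-cell experiment
scatters around the population value of ~0.67 (this seed drew 0.79;
the bootstrap spread shows why replicates matter), and with noise
variant 0 (no resampling) the same experiment gives a correlation
indistinguishable from zero.

A model fit from the shell:

```bash
burstabc simulate --config config.yaml --seed 7 --out data/
burstabc fit data/traces.csv --config config.yaml --seed 1 --out fit/
burstabc global-fit series.csv --config config.yaml --seed 1 --out gfit/
```

`fit/posterior.csv` holds one row per particle (model code, parameters,
distance) and `fit/model_frequencies.csv` the posterior model
frequencies.

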
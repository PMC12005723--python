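# pulseddm

Joint neural-behavioral modeling of pulse-based evidence accumulation.
A bounded drift-diffusion accumulator, driven by adapted auditory click
pulses, is fit by maximum likelihood *simultaneously* to spike trains
(Poisson or negative-binomial observations through softplus tuning curves
with time-varying baselines) and binary choices (threshold rule with
lapses).  The latent distribution is propagated by a discretized
Fokker-Planck (Markov) operator with absorbing bounds; forward-backward
smoothing yields posteriors over the accumulator, which support choice
decoding, change-of-mind detection, and model comparison.

## Package layout

| module | contents |
| --- | --- |
| `pulseddm.stimulus` | click trains, sensory adaptation, half-offset click/spike binning |
| `pulseddm.latent_fp` | latent grid, transition operator, distribution propagation |
| `pulseddm.observations` | softplus tuning, RBF baselines, Poisson/NB log-pmfs, lapse choice rule |
| `pulseddm.inference` | joint / choice-only / independent-noise likelihoods, L-BFGS-B fitting, Laplace CIs, k-fold splits, null models, bits/trial |
| `pulseddm.posterior` | forward-backward posteriors, choice decoding, Bernoulli & Poisson GLM baselines |
| `pulseddm.analyses` | PSTHs and R², shuffle-corrected cross-correlations, psychometrics, change-of-mind detection, participation ratio, neuron selection |
| `pulseddm.synthetic` | synthetic session generation (fine-step SDE and model-matched generators), recovery reports |
| `pulseddm.session` | JSON session file format (clicks, spikes, choices, neuron registry) |
| `pulseddm.experiments` | end-to-end validation experiments used by the acceptance checks |
| `pulseddm.cli` | `pulseddm` command-line interface |

## CLI

```bash
pulseddm simulate --seed 7 --trials 500 --out session.json
pulseddm fit --model joint --obs poisson --data session.json --seed 1 --out fit.json
pulseddm posterior --fit fit.json --data session.json --condition spikes+choice --out post.json
pulseddm decode --fit fit.json --data session.json --baseline glm
pulseddm analyze --what psychometric --data session.json --out report/
pulseddm recover --seeds 1..5 --trials 200 --neurons 3 --out recovery.csv
pulseddm bin --data session.json --dt 0.01 --out binned.json
```

Session files are JSON (format_version 1): a neuron registry (id, region,
response latency) plus per-trial left/right click times, duration, choice,
and per-neuron spike times.  Different trials may list different neurons;
only neurons recorded on a trial contribute to its likelihood.

## Notes on defaults

Latent grid n = 53 bins, dt = 10 ms, Gaussian spreads truncated at 4 SD on
a refined sub-grid (factor 10) and settled onto the two nearest bins;
optimization domain follows the published parameter box (variance bounds
configurable); spike bins are offset by dt/2 relative to click bins, with
per-bin exposures at the trial edges.
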
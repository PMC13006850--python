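# somnocog

Analysis pipeline for **multi-night, in-home sleep EEG and next-day cognition**
studies with wearable headband devices: slow-oscillation (SO) and sleep-spindle
detection on frontal-occipital derivations, macro/micro sleep-architecture
metrics, executive-task scoring (Go/NoGo, Simon switch), and the mixed-model
statistical layer that links nightly sleep quality to next-day performance.
A first-class synthetic-data generator makes every stage verifiable by
recovery against injected ground truth, without any real recordings.

## Who this is for

Sleep researchers running repeated-measures protocols (one participant, many
nights) with portable EEG — where channel quality varies night to night, a
fraction of nights must be excluded, and the scientific questions are posed as
participant-random-intercept GLMMs and intraclass correlations rather than
single-night group contrasts.

## The models at the core

**Event detection.** EEG (250 Hz, μV) is bandpassed 0.3–40 Hz (300th-order
zero-phase FIR), cut into 30-s epochs, demeaned, and epochs exceeding 200 μV
or not scored N2/N3 are masked out. On the 0.3–4 Hz trace, a slow oscillation
is a negative-then-positive half-wave pair between zero crossings with
trough ≥ 33 μV, trough-to-peak ≥ 61 μV, negative half-wave 125–1500 ms and
positive half-wave ≤ 1000 ms. Spindles are detected by a sliding-window
(0.3 s window, 0.1 s step) sigma-feature rule: relative 11–16 Hz power,
sigma-broadband correlation, and sigma-broadband covariance must all exceed
their thresholds; merged candidates of 0.5–2.5 s are kept. Densities are
events per minute of N2+N3.

**Statistics.** For outcome $y_{ij}$ of participant $i$ on day $j$:

$$y_{ij} = \beta_0 + \mathbf{x}_{ij}^\top\boldsymbol\beta + u_i + \varepsilon_{ij},
\qquad u_i \sim \mathcal N(0, \sigma^2_b),\ \varepsilon_{ij} \sim \mathcal N(0, \sigma^2_w),$$

fitted by maximum likelihood, with a zero-inflated beta variant (logit link,
constant inflation) for proportion outcomes such as commission-error rates.
Reliability is the intraclass correlation
$\mathrm{ICC} = \sigma^2_b / (\sigma^2_b + \sigma^2_w)$ with a parametric-
bootstrap CI; beta-family models use the latent-scale ICC
$\sigma^2_b/(\sigma^2_b + 1)$. Benjamini–Hochberg FDR correction, Type III
tests, and Monte-Carlo power curves round out the layer.

## Worked example

```python
import numpy as np
from somnocog import (
    EventInjectionSpec, HypnogramSpec, calibrated_transition_matrix,
    generate_hypnogram, synthesize_night, fir_bandpass, build_analysis_mask,
    detect_slow_oscillations, detect_spindles, icc_from_variances,
)
from somnocog.config import default_config

sim = default_config()["simulate"]
P = calibrated_transition_matrix(sim["stage_target_min"], sim["stage_dwell_epochs"])
hyp = generate_hypnogram(HypnogramSpec(P, "W", n_epochs=240, seed=1))
night, truth = synthesize_night(hyp, EventInjectionSpec(seed=2))

filt = fir_bandpass(night.signal[0], 250, 0.3, 40, 300)
mask = build_analysis_mask(night, "F7-O1", hyp, 200, prefiltered=filt)
so = detect_slow_oscillations(filt, 250, mask)
sp = detect_spindles(filt, 250, mask)
minutes = hyp.minutes_in("N2", "N3")
print(f"SO density {len(so)/minutes:.2f}/min "
      f"(injected {sum(e.type=='SO' for e in truth)/minutes:.2f}/min), "
      f"mean p2p {np.mean([e.p2p_uV for e in so]):.1f} uV")
print(f"spindle density {len(sp)/minutes:.2f}/min")
print(f"ICC from variance components: {icc_from_variances(2404.27, 1440.80):.2f}")
```

prints

```
SO density 4.63/min (injected 4.69/min), mean p2p 87.7 uV
spindle density 1.48/min
ICC from variance components: 0.63
```

— the detectors recover the injected event rates on a two-hour synthetic
night, measured SO amplitudes sit at the ~86 μV scale typical of older-adult
frontal derivations, and the variance components of a
reaction-time-style model give a between-participant reliability of 0.63.

There is also a CLI for end-to-end runs:

```bash
somnocog run --config sim.yaml --out run_dir --seed 7     # simulate→detect→model
somnocog detect --edf night.edf --hyp night.hyp.csv --out events.csv
```

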
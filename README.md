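# optokinetics

Quantitative analysis of **signal persistence** in receptor signaling
networks under optogenetic control.  When a light-gated antigen receptor
(an optically switchable CAR in T cells conjugated to presenting cells) is
switched off, how fast do the downstream signals — intracellular Ca²⁺,
doubly phosphorylated ERK, active FOS transcription factor, nascent mRNA,
and finally protein output — dissipate?  The package provides the kinetic
models, curve-fitting procedures and data-reduction pipelines to answer
that question from flow-cytometry event tables, Western lane profiles,
qPCR Ct tables and two-channel microscopy movies, plus a pulse-train
simulator for the signal-integration logic of pulsatile stimulation and
seeded synthetic-data generators so the entire chain runs and validates
itself with no external data.

It is written for quantitative cell biologists and systems-biology analysts
who want reusable, tested implementations of these estimators rather than
one-off notebook code.

## The model

The network between receptor and readout is a linear chain of k identical
mass-action steps with per-step rate r = 1/θ:

    dx₁/dt = r(u(t) − x₁),    dxᵢ/dt = r(xᵢ₋₁ − xᵢ)

With input removed at t = 0 from steady state, the terminal node decays as
the **survival function of a gamma(k, θ) distribution**:

    S(t) = Q(k, t/θ) = e^(−t/θ) Σᵢ₌₀^(k−1) (t/θ)ᵢ / i!   (integer k)

Fitting S(t) over integer shapes to a normalized decay trace yields the
effective number of network steps (k), the per-step timescale (θ), the
half-life (survival quantile at 0.5) and the onset time (quantile at 0.99,
the time for shutoff information to propagate through the chain).  k = 1
recovers the single-exponential special case used for the receptor's own
dissociation/re-association phases.  Downstream, a thresholded (Hill)
transcription readout, a first-order mRNA stage and a delayed first-order
protein stage turn cascade activity into 24-h gene-expression endpoints for
pulse-frequency-modulated stimulation protocols.

## Worked example

Recover the calcium-decay kinetics from a synthetic conjugate experiment —
gating double-positive conjugates, computing background-subtracted Indo-1
ratios, binning a 2-s mean trace, normalizing to relative calcium and
fitting gamma survival functions:

```
python analysis/02_calcium_persistence.py
```

prints

```
gated 30.07% of events as conjugates (18047 events)
gamma-survival fit: k = 5, theta = 6.08 s
half-life 28.4 s (95% CI 27.3-28.3), onset 7.8 s
wrote results/calcium_fit.json
```

meaning: the pipeline identified a five-step effective cascade with a ~6-s
per-step timescale; after illumination the calcium signal takes ~8 s to
begin falling (1% decrease) and halves in ~28 s — recovering the kinetics
the events were generated with (k = 5, θ = 6.21 s, half-life 29 s).  The
same pattern holds for the other analyses:

| script | question | readout |
| --- | --- | --- |
| `analysis/01_receptor_kinetics.py` | how fast does the receptor itself switch? | exponential rates of both phases, 95%-completion times |
| `analysis/03_downstream_halflives.py` | how long do ppERK and active FOS persist? | median time course and lane-profile active fraction half-lives |
| `analysis/04_mrna_decay.py` | how long does mRNA persist after transcription halts? | light/dark ratio decay per gene |
| `analysis/05_pulse_integration.py` | do spaced pulses integrate into more output? | 24-h endpoints vs. inter-pulse interval, with bounds |
| `analysis/06_plate_calibration.py` | is the illumination hardware uniform? | per-well linear calibration, scaled to the dimmest well |

Each writes tidy CSV/JSON under `results/`.  The same pipelines are exposed
as a CLI (`optokinetics fit-calcium --seed 1 --out runs/ca`) and as plain
library functions (`optokinetics.kinetics_fit.fit_gamma_survival`, ...).

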
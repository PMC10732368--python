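# bimanual-adapt

Simulation and analysis of **bimanual curl-field adaptation** experiments,
for motor-control researchers studying how the sensorimotor system encodes
a motor memory across the two arms.

## The paradigm

A planar robot applies a velocity-dependent curl force field to the **left**
hand whose magnitude is driven by the **right** hand's velocity:

```
[Fx, Fy]_left = [[0, -B], [B, 0]] · [vx, vy]_right,      B = 13 N·s/m
```

Participants make simultaneous reaches of both hands across combinations of
three speed classes (15/20/25 cm reaches at desired peak speeds of
45/60/75 cm/s, one shared movement time), through baseline, exposure and
generalization phases (2208 trials). Interleaved **error-clamp (channel)
trials** (stiffness 6000 N/m, damping 20 N·s/m) confine the left hand to a
straight path so the predictive lateral force can be measured. A training
group with mismatched hand speeds can observe the right-hand dependence
(*evident*); a matched-speed group cannot (*ambiguous*).

The learned motor memory is characterised by fitting four encoding models to
the clamp-trial forces **F** as a function of each hand's forward speed:

```
right:     F = α · v_R · B
left:      F = α · v_L · B
average:   F = α · (v_L + v_R)/2 · B
weighted:  F = α · (ω·v_R + (1−ω)·v_L) · B         (ω unrestricted)
```

ω = 1 is pure right-hand encoding (the environment's true mapping), ω = 0
pure left-hand encoding. Models are compared by a Gaussian-likelihood BIC,
`n·ln(SSE/n) + k·ln(n)`, against a zero-parameter reference with a fixed
gain (the mean fitted α pooled over models and participants). Adaptation is
quantified by **force compensation** (the through-origin regression slope of
measured on perfect-compensation force, `+B·v_R`, in %) and the **maximum
perpendicular error** of the hand path.

Because no public dataset accompanies the paradigm, the package includes a
full synthetic-experiment generator: block-randomized schedules,
minimum-jerk reaches with peak-speed noise and a small right-hand lead, the
coupled field/channel dynamics, and a single-rate adaptive learner with a
ground-truth encoding weight — so every analysis stage is exercisable and
testable end to end.

## Worked example

```python
import bimanual_adapt as ba

cfg = ba.RunConfig(seed=1, n_participants_per_group=2, output_dir="results/demo",
                   analysis=ba.AnalysisOptions(fit_weight_trajectory=False))
tables = ba.run_pipeline(cfg)

trained = tables["fits"][tables["fits"].scope == "trained"]
print(trained.groupby(["group", "model"])[["omega", "delta_bic", "r2"]].mean().round(3))
```

```
                         omega  delta_bic     r2
group     model
ambiguous average          NaN   7806.649  1.000
          left             NaN   1959.416  0.997
          nonparametric    NaN      0.000  0.993
          right            NaN     17.522  0.993
          weighted       0.398  11014.022  1.000
evident   average          NaN  -6516.655  0.944
          left             NaN -10347.891  0.723
          nonparametric    NaN      0.000  0.996
          right            NaN     -4.761  0.996
          weighted       0.896   9654.657  1.000
```

The simulated evident group (ground-truth ω = 0.9) is recovered with strong
right-hand encoding, the ambiguous group (ω = 0.4) with mixed encoding
tending toward the left hand; `delta_bic` is the BIC improvement over the
fixed-gain reference (positive = better), and the weighted model wins in
both groups. Mean generalization-phase force compensation in the same run is
80.2% (evident) and 81.6% (ambiguous), i.e. close to the learner's
configured 0.8 asymptote.

A CLI mirrors the library (`bimanual-adapt simulate | analyze | report`);
`analyze --dataset <csv>` runs the identical pipeline on recorded data in
the package's tidy long format (see `bimanual_adapt.io`).

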
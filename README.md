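# headingbayes

Humans judging their direction of self-motion (heading) from optic flow
are systematically biased — but the literature disagrees on the sign:
some studies find headings compressed toward straight ahead (center
bias), others find them pushed outward (peripheral bias). A key
confound is the **response range**: how wide an arc, line or circle the
participant is given to point out their answer. Estimates scale with
that range, turning underestimation into overestimation as the probe
widens.

`headingbayes` implements an efficient Bayesian observer model of
heading estimation with a response-range-dependent perception-action
stage, for psychophysicists who want to fit trial-level heading reports,
predict bias/variability curves, and run synthetic experiments.

## Model

Perception is efficient Bayesian inference on the circle:

- **Prior** p(θ): a two-peak von Mises mixture over heading θ, peaked at
  straight ahead (0°) and straight back (180°). Under efficient coding
  the prior is inversely proportional to the discrimination threshold,
  p(θ) ∝ 1/D(θ), so it can also be fitted from threshold data.
- **Encoding** F(θ) = ∫₋π^θ p(ϑ) dϑ: the cumulative prior maps stimulus
  space to a sensory space with uniform Fisher information (rescaled to
  the sensory circle, F̃ = 2πF − π).
- **Measurement** m = F̃(θ₀) + η with von Mises noise η of concentration
  κ, giving the likelihood p(m|θ) = exp(κ cos(m − F̃(θ))) / (2π I₀(κ)).
- **Decoding**: the posterior p(θ|m) ∝ p(m|θ) p(θ) is summarized by its
  circular mean θ̂(m) (the L2-optimal estimate).
- **Perception-action mapping**: the report is θ̂ᵣ = αᵢ · θ̂, linearly
  scaled about straight ahead with one factor αᵢ per response-range
  condition, clipped to the probe's interval [−range/2, +range/2].

Predicted bias and spread marginalize the report over the measurement
distribution: b(θ₀) = E[θ̂ᵣ|θ₀] − θ₀ and the circular standard deviation
σ(θ₀) = √(2(1 − R)), with R the mean resultant length of θ̂ᵣ.

The model has four free parameters per fit — κ shared across conditions
and one α per condition — estimated jointly by maximum likelihood
(Eq: argmax p(data | κ, α₁, α₂, α₃)) with multi-start derivative-free
search plus an exact profile-likelihood polish.

## Worked example

Simulate one participant's interleaved three-probe session (80°/160°/240°
arcs, 12 headings × 15 repetitions = 540 trials) from known parameters,
then fit the model back:

```python
import headingbayes as hb

design = hb.make_design("exp3")                 # arc80/arc160/arc240, 540 trials
prior  = hb.build_prior(resolution=512)
trials = hb.generate_trials(
    design, prior,
    hb.ObserverParams(4.0),                     # sensory concentration kappa
    hb.ResponseMapping({"arc80": 0.85, "arc160": 1.0, "arc240": 1.15}),
    seed=11, n_participants=1,
)

model  = hb.HeadingObserverModel(trials)
result = model.fit(seed=1)
print(result.summary())
```

```
Heading observer model — maximum likelihood fit
=======================================================
level:           group
n trials:        540
log-likelihood:  -2321.785
AIC:             4651.570
converged:       True   (restarts: 5, seed: 1)
floored trials:  0
-------------------------------------------------------
parameter               estimate
kappa (sensory)           4.3819
alpha arc160              1.0046
alpha arc240              1.1501
alpha arc80               0.8949
=======================================================
```

The generating parameters (κ = 4, α = 0.85 / 1.00 / 1.15) are recovered
within a few percent, and the fitted α increase with the response range.
The descriptive analysis shows the corresponding bias-slope reversal in
the raw reports — negative slope (center bias) on the narrow probe,
positive slope (peripheral bias) on the wide one:

```python
print(result.empirical_slopes().to_string(index=False))
```

```
condition_label     slope  intercept
         arc160  0.154241   1.363269
         arc240  0.464484  -1.751235
          arc80 -0.107740   2.146907
```

`result.predict()` returns the model's bias/SD curves per condition and
`result.plot()` overlays them on the empirical curves.

### Command line

The same pipeline is available as a CLI:

```bash
headingbayes simulate --experiment exp3 --seed 7 --out-dir out/sim
headingbayes fit      --trials out/sim/trials.csv --out-dir out/fit
headingbayes predict  --fit-result out/fit/fit_group.yaml --out-dir out/pred
headingbayes analyze  --trials out/sim/trials.csv --out-dir out/ana
```

Every run writes its effective configuration and log next to its
outputs; with fixed seeds the whole chain is bit-reproducible.

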
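# kalmantd

Associative learning as the tracking of a changing value distribution:
a simulator for four classical-conditioning models — the
**Rescorla-Wagner** rule, the **Kalman filter**, **temporal-difference
(TD) learning**, and their synthesis, **Kalman TD** — together with a
compact textual notation for conditioning designs and a catalog of the
cue-competition, retrospective-revaluation and serial-compound paradigms
that dissociate the models.

It is written for computational-neuroscience and animal-learning
researchers who want executable, testable versions of these models'
predictions: every update equation is a pure function, every model is a
scikit-learn-style estimator, and every paradigm's predicted response
ordering is a machine-checkable constraint.

## The models

All four models learn a weight vector **w** linking stimulus features
**x** to reward. On each observation:

* **Rescorla-Wagner** (point estimate, immediate reward):
  δₙ = rₙ − **w**ᵀ**x**ₙ and **w** ← **w** + α **x**ₙ δₙ. With the
  Robbins-Monro schedule αₙ = α/n it converges to the maximum-likelihood
  (least-squares) weights.
* **Kalman filter** (Bayesian, immediate reward): the agent assumes a
  linear-Gaussian dynamical system — **w**₀ ~ N(0, σ_w² I), weight drift
  **w**ₙ ~ N(**w**ₙ₋₁, τ² I), reward noise rₙ ~ N(**w**ₙᵀ**x**ₙ, σ_r²) —
  and tracks the full Gaussian posterior N(ŵ, Σ). The Kalman gain
  **k**ₙ = (Σₙ+τ²I)**x**ₙ / (**x**ₙᵀ(Σₙ+τ²I)**x**ₙ + σ_r²) is a
  stimulus-specific, uncertainty-weighted learning rate; negative
  off-diagonals of Σ couple cues trained in compound and drive
  retrospective revaluation (backward blocking, unovershadowing, …).
* **TD(0)** (point estimate, long-term reward): over a complete serial
  compound (CSC) representation — each stimulus split into time bins,
  one feature per (stimulus, bin) — it learns the value
  V(**x**ₜ) = **w**ᵀ**x**ₜ of expected discounted future reward via
  δₜ = rₜ + γ**w**ᵀ**x**ₜ₊₁ − **w**ᵀ**x**ₜ.
* **Kalman TD** (Bayesian, long-term reward): the Kalman filter applied
  to the discounted temporal derivative **h**ₜ = **x**ₜ − γ**x**ₜ₊₁,
  for which rₜ = **w**ᵀ**h**ₜ is exactly the TD consistency condition.
  It inherits TD's within-trial structure and second-order conditioning
  and the Kalman filter's uncertainty tracking and revaluation.

## Design notation

Experiments are written the way the conditioning literature abbreviates
them: uppercase letters are stimuli, `AB` a simultaneous compound,
`Z→X→+` a serial compound ending in reward, `-` no reward, `?` a test
probe, `/` interleaves trial types within a phase, `;` separates phases.
ASCII `->` is accepted for `→`. For example, forward blocking with an
unblocking control:

```
blocking:   A→+; AB→+; B→?
unblocking: A→+; AB→+; A→-; B→?
```

## Worked example

```bash
$ kalmantd run forward_blocking
# parameters: ModelParams(alpha=0.3, gamma=0.98, sigma_w2=1.0, sigma_r2=1.0, tau2=0.01, bins_per_stimulus=4, lr_schedule='constant')
 condition model probe  response
  blocking    KF     B  0.061967
unblocking    KF     B  0.475607
            lhs op           rhs  margin  passed                                           note
unblocking/KF/B  > blocking/KF/B 0.41364    True extinction of the blocking stimulus recovers B
```

The response is the reward expectation **w**ᵀ**x** for the probe under
the final posterior mean. After A→+ then AB→+, B alone evokes almost no
expectation (0.062): A blocked it. Extinguishing A afterwards (A→-)
raises B's expectation to 0.476 without B ever being presented — the
negative covariance acquired during compound training lets evidence
against A count as evidence for B. The ordering table confirms the
paradigm's predicted direction (margin 0.414), and the process exits 0;
a violated prediction exits 2.

The same from Python, composing with any scikit-learn tooling:

```python
from kalmantd import KalmanFilter, parse_design, run_model

run = run_model(parse_design("A→+; AB→+; A→-; B→?"), model="KF")
run.responses          # {'B→?': 0.4756...}
run.estimator.Sigma_   # full posterior covariance
run.trace              # tidy per-step, per-feature DataFrame
```

`kalmantd list` prints the ten-paradigm catalog (latent inhibition, the
overshadowing/blocking/overexpectation/conditioned-inhibition recovery
quartet, and five serial/second-order paradigms that dissociate Kalman
TD from TD), and `kalmantd sweep` grids any parameter:

```bash
$ kalmantd sweep latent_inhibition -p tau2 -v 0.005,0.02
 tau2  all_pass  no_pre/KF/A  pre/KF/A
0.005      True     0.917577  0.589918
0.020      True     0.937277  0.766851
```

More diffusion (τ²) keeps uncertainty — and hence the gain — higher, so
pre-exposure loses its grip: latent inhibition weakens.

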
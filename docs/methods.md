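# Methods

This note documents the modelling assumptions, numerical choices and
known limitations of the simulator. It is the package's own account of
its science; every empirical statement here is computed by the test
suite or the acceptance script.

## Generative model and learning rules

All models operate on feature/reward observation streams. The Bayesian
models assume a linear-Gaussian dynamical system: a Gaussian prior
w₀ ~ N(0, σ_w² I) over associative weights, a Gaussian random-walk drift
wₙ ~ N(wₙ₋₁, τ² I) between trials, and Gaussian reward noise
rₙ ~ N(wₙᵀxₙ, σ_r²). The Kalman filter is exact inference for this
model; `batch_posterior_oracle` implements the equivalent conjugate
batch posterior for static weights (τ² = 0),
Σ = (I/σ_w² + XᵀX/σ_r²)⁻¹, μ = ΣXᵀr/σ_r², and the test suite verifies
the recursive filter reproduces it to 1e-8 on random design matrices.
The point-estimate models (Rescorla-Wagner, TD) follow the same error
signals without tracking Σ; with the 1/n Robbins-Monro schedule,
Rescorla-Wagner converges to the maximum-likelihood weights (verified
against the OLS solution of a 3-feature Gaussian generator at 10⁵
samples, tolerance 1e-2).

## Parameters

| parameter | default | units / range | role |
|---|---|---|---|
| σ_w² | 1.0 | squared reward units | prior weight variance; initial gain scale |
| σ_r² | 1.0 | squared reward units | reward noise; larger ⇒ slower learning |
| τ² | 0.01 | squared reward units per trial | weight drift; keeps gains from collapsing |
| α | 0.3 | [0, 1] | learning rate of RW and TD |
| γ | 0.98 | [0, 1] | discount of the real-time models |
| bins_per_stimulus | 4 | — | CSC temporal resolution |

Every catalog paradigm runs 10 trials per trial type per phase, reward
magnitude 1. These are the standard settings of the simulation
literature this package follows; the CLI logs the resolved set on every
run so deviations are auditable.

## Temporal representation

Real-time models use the complete serial compound: each stimulus owns
`bins_per_stimulus` consecutive feature columns, the b-th active only at
the b-th step after that stimulus's onset. Feature identity is per
(stimulus, bin) — a stimulus reuses its columns wherever it appears in a
trial. Serial events are concatenated without overlap: in Z→X→+ with 4
bins, Z's bins occupy steps 1–4 and X's steps 5–8, matching the
notation's meaning of "Z terminates at X's onset". Reward arrives at the
trial's final step; no inter-trial-interval steps are simulated.

Kalman TD observes the discounted derivative hₜ = xₜ − γxₜ₊₁, with the
successor taken as zero at each trial's last step (no leakage across
trials). We orient h so that reward-predictive cues get positive
weights, i.e. rₜ = wᵀhₜ is the fixed point of the TD error
δₜ = rₜ + γwᵀxₜ₊₁ − wᵀxₜ; the opposite orientation is available as
`derivative_sign="flipped"` and merely negates the weights. γ = 0
collapses TD onto Rescorla-Wagner and Kalman TD onto the Kalman filter,
step for step; both reductions are asserted exactly in the tests.

## Diffusion timing

The generative drift is per trial, so the τ²·I predict step is applied
once per observation for trial-level models and once at each trial's
first time step for real-time models (`KalmanTD(diffusion="trial")`, the
default). Applying it at every CSC step instead
(`diffusion="step"`) makes uncertainty grow with trial *length* — a
10-trial phase of 4-bin trials would accrue 0.4 of variance against a
prior of 1 — which washes out pre-exposure effects: serial latent
inhibition reverses under that timing. Per-trial diffusion reproduces
it.

Test probes never update the model; the response readout is wᵀx for
trial-level models and the onset-bin value wᵀx_onset for real-time
models (value at stimulus onset is the conventional anticipatory-response
proxy). Uncertainty growth over an unobserved retention interval is
modelled explicitly by `kalman_predict` / `estimator.diffuse(n_steps)`;
the tests show pre-exposure gains fall monotonically and recover after
such an interval.

## Numerical choices

The covariance update Σ' = S − k xᵀ S (S = Σ + τ²I) is explicitly
re-symmetrized each step; the Joseph form
(I − kxᵀ)S(I − kxᵀ)ᵀ + σ_r² kkᵀ is available behind `joseph=True` and
agrees to 1e-10 on random streams. Symmetric positive
semi-definiteness (eigenvalues ≥ −1e-8) is asserted property-style.
Within-phase trial ordering defaults to deterministic round-robin
alternation, making every run bit-reproducible; a seeded `shuffled`
schedule is provided, and equality constraints between conditions are
checked at 1e-9.

## What the catalog does and does not show

The ten catalog paradigms encode directional predictions only — the
models claim orderings of test responses across conditions, not
quantitative fits to any animal dataset. Inputs are noiseless binary
designs; real conditioning data add motivational, stimulus-intensity
and response-scaling factors that these simulations deliberately omit.
Passing the ordering suite therefore shows the models' qualitative
logic is implemented correctly, not that they fit behaviour.

Nineteen of the twenty ordering constraints hold at the defaults. The
exception is deliberate and instructive: in the serial-recovery
paradigm (Z→X→+ / W→Y→+; Z→-; X→? / Y→?), the claim that extinguishing
the leading element Z *raises* its partner X above the control Y is not
producible by Kalman TD under the non-overlapping serial representation.
Training observations h = Z₃ − γX₀ (r = 0) enforce the chain constraint
w_Z₃ ≈ γw_X₀ and thereby couple Z's last bin and X's onset bin with
*positive* posterior covariance, so extinguishing Z drags X down — and
this is not a filter artifact: the exact conjugate batch posterior on
the same observations puts X's onset weight (0.199) below Y's (0.298).
An overlapping (co-terminating) serial representation does reverse this,
because simultaneously active elements compete for the same reward and
acquire negative covariance, but it simultaneously reverses the
serial-extinction and serial-latent-inhibition predictions. No single
representation satisfies all six serial predictions at once; we keep the
representation the notation defines, leave this one constraint failing
in the report (the CLI exits 2 on it), and flag it as a modelling
boundary worth experimental attention.

## Limitations

* Serial-chain effects attenuate with temporal resolution: at 8 bins per
  stimulus, 10 trials propagate almost no value across a 16-step chain
  (probe onset values ≈ 0.01) and three serial orderings lose their
  sign. The ordering pattern is stable for 2–4 bins and for ±50%
  perturbation of τ², which the tests assert.
* No context stimuli, stimulus intensities other than 0/1, probabilistic
  reinforcement, trace decay or basis-function temporal representations.
* Learning rate is uncertainty-driven only: surprise-modulated
  associability (Pearce-Hall-style τ learning) and action selection are
  out of scope.
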
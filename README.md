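# cosmospot

Bayesian spot-probability analysis for colocalization single-molecule
spectroscopy (CoSMoS) image stacks.

In a CoSMoS experiment, surface-tethered *target* molecules are mapped, and
fluorescently labeled *binder* molecules arriving at those locations produce
diffraction-limited spots in a time series of TIRF images. The scientific
question per target location and frame is binary — is a **target-specific**
spot present? — but a hard yes/no answer discards the genuine ambiguity of
noisy images and of spots that colocalize with the target only by chance.
`cosmospot` instead fits a holistic generative model of the images and
reports the posterior probability **p(specific)** for every AOI (area of
interest) and frame, then propagates those probabilities into equilibrium
(`Keq`) and kinetic (`kon`, `koff`, time-to-first-binding) constants with
calibrated uncertainties.

## The model

Each P×P AOI image is modeled as

```
D = δ + I,   I ~ Gamma(mean = μ_I, var = μ_I · g)
μ_I = b + Σ_k m_k · h_k/(2π w_k²) · exp(−((i−x_k−x_t)² + (j−y_k−y_t)²)/(2 w_k²))
```

with an empirical camera-offset distribution δ, gain g, background b, and up
to K Gaussian spots (default K = 2). Latent indicators say which spots exist
(`m`) and whether one of them is target-specific (`z`, index `θ`); specific
spots are colocalized with the target through a mean-zero position prior
with sd `σ_xy` (the *proximity*), nonspecific spots land uniformly. Priors
and variable domains are documented in `docs/methods.md`.

Inference is stochastic variational: the discrete latents and the offset are
enumerated **exactly** (8 admissible `(z, θ, m)` combinations for K = 2),
every continuous latent gets a transformed-Gaussian mean-field factor, and
the ELBO is maximized with Adam on mini-batches using hand-derived
reparameterized gradients (NumPy + a compiled Numba kernel). `p(specific)`
is a Monte-Carlo average (S = 25) of the exact enumerated conditional
`p(z, θ | φ′, D)` under the fitted guide.

## Worked example

`examples/02_fit_spot_probabilities.py` simulates a small dataset (5
on-target + 5 control AOIs × 60 frames at SNR 3.76, π = 0.15, λ = 0.15) and
fits it:

```
converged: False after 800 iterations
  pi        posterior  0.196 [0.143, 0.248]  truth 0.15
  lam       posterior  0.160 [0.124, 0.194]  truth 0.15
  g         posterior  7.116 [6.757, 7.598]  truth 7.0
  sigma_xy  posterior  0.582 [0.486, 0.670]  truth 0.5
recall 1.000  precision 0.918  MCC 0.948
```

Each line shows the posterior mean and 95% highest-density interval of a
global parameter next to the value used to generate the data: the binding
probability π, nonspecific density λ, camera gain g and proximity σ_xy are
all recovered within their intervals from 600 on-target frames. The last
line thresholds p(specific) at 0.5 and scores it against the known truth —
at this SNR essentially every specific spot is found (recall 1.0), with a
handful of chance colocalizations scored as specific (precision 0.92).

The other examples cover simulation and SNR accounting (`01`), kinetic-rate
and equilibrium-constant estimation from probabilistic records (`03`), and
probabilistic rastergrams (`04`). A `cosmospot` command-line interface
(`simulate`, `fit`, `stats`, `kinetics`, `show`) wraps the same library for
shell pipelines.

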
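# Methods

## Signal model and pipeline

The package treats a throat-vibration recording as a uniformly sampled
real series x₁…x_T (sensor voltage, arbitrary units). Denoising is
window-wise reconstruction: the signal is embedded as the L×K trajectory
(Hankel) matrix with column j = x[j..j+L−1], each column is z-scored, a
learned network maps each noisy window to an estimate of the clean
window, the z-scoring is inverted with the stored per-column statistics,
and the stack of overlapping window estimates is collapsed by
anti-diagonal (diagonal) averaging. On Hankel input diagonal averaging is
the exact inverse of the embedding, which the test suite checks to
1e−12; on network output it averages the L independent estimates
available for each sample, attenuating uncorrelated per-window error.

The z-scoring uses the population standard deviation (divide by n).
Constant windows are handled by flooring σ at 1e−8, mapping them to
all-zero normalized columns instead of dividing by zero. Anti-diagonal
bookkeeping is 0-based internally; the count of entries on anti-diagonal
t is the ramp/flat/ramp piecewise function min(t+1, min(L,K), L+K−1−t).

An optional STFT stage (Hanning window, w[n] = ½ − ½cos(2πn/(N−1)),
default N = 256, hop H = 64, i.e. 75 % overlap) can pre-suppress
stationary noise before the network: per frequency bin, magnitudes are
soft-thresholded against a noise floor estimated as the 0.10 quantile of
that bin's magnitude across frames, with a minimum retained gain of 0.05
and phase untouched. The mask is **off by default**: its mechanism is a
design choice of this package, and the documented pipeline without it is
fully determined by the equations of the embedding and the network.
Frames start at sample 0 with no padding; synthesis is windowed
overlap-add normalized by the accumulated squared window, so interior
samples (≥ N from either edge) reconstruct to better than 1e−10.

## The DBN reconstructor

The network is a stack of three restricted Boltzmann machines. The first
layer has Gaussian visible units with per-unit scales σᵢ (energy
E(v,h) = Σ(vᵢ−aᵢ)²/2σᵢ² − Σbⱼhⱼ − Σ(vᵢ/σᵢ)Wᵢⱼhⱼ), suited to the
continuous z-scored windows; upper layers are Bernoulli–Bernoulli. Both
energies give the conditional P(hⱼ=1|v) = sigmoid(bⱼ + Σᵢ(vᵢ/σᵢ)Wᵢⱼ);
the Gaussian conditional mean is E[v|h] = a + σ⊙(Wh). Default widths are
64 → 256 → 128 → 64 with a linear head back to 64; the topology (three
RBMs plus a regression layer) is fixed, the widths are free parameters.

**Pre-training** is greedy and unsupervised: each layer is trained by
CD-1 (configurable k) with plain SGD at rate 1e−3, on the previous
layer's hidden probabilities. Hidden states are sampled with seeded
Bernoulli draws. Visible reconstructions use the conditional mean for
Gaussian units — the usual low-variance choice, since sampling would
only add noise scaled by σ — but are sampled for Bernoulli units: with
sampled visibles the Gibbs chain is stationary on model-distributed
data, so the expected CD update is exactly zero at the maximum-likelihood
fixed point, which the suite verifies statistically, along with the
positive inner product between the expected CD-1 direction and the exact
enumerated log-likelihood gradient on toy models. Adam is deliberately
absent from this stage. σ is held at 1 (inputs are already z-scored).

**Fine-tuning** attaches the affine head and backpropagates the joint
loss L = λ₁·MSE + λ₂·(mean absolute difference of full-DFT magnitude
spectra), λ₁ = 0.7, λ₂ = 0.3, through the deterministic sigmoid stack.
Both loss terms are mean-reduced per element so the λ weights compare
like with like. The spectral term's gradient is computed analytically —
for X = F x̂ the derivative of |X_k| maps back through Re(ifft(s·X/|X|))
with the subgradient 0 at zero magnitude — and is validated against
finite differences. Visible biases and σ do not enter the deterministic
forward pass and are not updated during fine-tuning.

The optimizer is Adam written out explicitly: first/second moment
accumulators with bias corrections 1−β₁ᵗ, 1−β₂ᵗ and step
−α·m̂/(√v̂+ϵ), with β₁ = 0.9, β₂ = 0.999, ϵ = 1e−8. Closed-form
consequences used as tests: the first step has magnitude α/(1+ϵ); with
β₁ = β₂ = 0 the step is exactly −α·g/(|g|+ϵ); under a constant gradient
the per-step displacement converges to −α·sign(g). The learning rate
follows a breakpoint schedule, by default 5e−3 halved to 2.5e−3 from
epoch 90 of 100. A fixed 80/20 train/validation split (seeded) produces
the per-epoch loss table.

Training pairs are (noisy, clean) windows; **both** are z-scored with the
noisy window's statistics, because at inference only the noisy statistics
exist. This means the network learns the mapping in the noisy window's
frame, and de-scaling reuses those statistics exactly.

## The CNN comparator

A 1-D convolutional encoder–decoder with the stack
conv15/64 → pool2 → conv11/128 → pool2 → conv7/256 → sigmoid attention
gate (1×1) → deconv5/128 → deconv7/64 → skip(3), trained with the same
Adam step, joint loss, batch handling, validation split and learning-rate
schedule as the DBN. Details the layer table leaves open are fixed as:
stride-1 zero-padded "same" convolutions, max-pooling of width/stride 2,
nearest-neighbour upsampling followed by a convolution for each deconv
stage, the skip source being the first convolution's activation added to
the last deconv output through a length-3 projection, and a final 1×1
projection to one output channel (required to emit a signal). Inputs
whose length is not a multiple of 4 are edge-padded and the output
cropped. All forward and backward passes are plain numpy (im2col);
gradients are finite-difference-checked in the tests.

## Synthetic data

No public recordings exist for this task, so training and benchmarking
use a generator that emulates the phenomenology of laryngeal PVDF
traces: voiced stretches are a harmonic series at f₀ with 1/k amplitude
decay, gated by raised-cosine onsets/offsets (20 ms); unvoiced stretches
retain 3 % residual amplitude; noise is white Gaussian at 0.1× the
voiced RMS plus a 2 Hz baseline-drift sinusoid at 0.2× the voiced RMS
with a seeded random phase; two channels with gains (1.0, 0.6) and
independent noise realizations add linearly. Defaults: 8 kHz, 2 s,
f₀ = 120 Hz, 8 harmonics, a five-segment voiced/unvoiced layout whose
last segment is louder (raised-tone phonation). The generator reproduces
amplitude structure, onsets and the two noise mechanisms; it does not
model articulation, formants, pitch variation, sensor nonlinearity or
motion artifacts, so passing benchmarks demonstrate the pipeline's
mechanics and its behaviour under this noise model, not performance on
live recordings.

The default training corpus is 2048 window pairs sampled from the 2 s
benchmark utterance (about 13 % of its distinct windows) — dense enough
that the learned mapping generalizes across the signal; training takes
seconds on one CPU.

## Benchmark behaviour and known limitations

On the default benchmark the fine-tuning loss falls by more than 80 %
within 100 epochs, the denoised signal correlates with the clean
reference better than the raw noisy signal does, and spectral flatness
drops by roughly two orders of magnitude. The composite score, however,
moves only a few points: with frames of 100 samples at 8 kHz a frame
spans ~1.5 pitch periods, so the *clean* signal's own intra-frame
variance saturates the LNE term for clean and noisy alike, and the white
perturbation (1 % of signal power) barely changes it. Under this noise
model even a perfect denoiser would gain only ≈ 4 points — the score's
flatness and correlation terms are the only movers. LNE separates
methods sharply only when the reconstruction is smooth on the frame
scale or the frame is short relative to the pitch period.

Other limitations: supervised fine-tuning requires paired clean/noisy
data, which live throat recordings do not provide (the synthetic
generator fills this gap here); the network input is the normalized
trajectory column, with the STFT mask available as an earlier optional
stage rather than as the network's feature space; and no rank truncation
of the trajectory matrix is performed — the embedding serves windowing,
not subspace separation.
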
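# Methods

This note records the models implemented in `qpigan`, the defaults chosen
where the design was open, and what the synthetic experiments do and do not
demonstrate.

## Forward imaging model (`qpigan.optics`)

A specimen is a pure-phase object: transmission `exp(iφ(r))` of a
unit-amplitude field.  Imaging proceeds by

1. exact scalar **angular-spectrum propagation** over the signed defocus
   distance (`exp(i2πd√(1/λ² − f²))` in the frequency domain, evanescent
   components zeroed);
2. low-pass filtering by the circular **objective pupil** of radius NA/λ;
3. squaring to intensity.

**Partial coherence.**  The condenser is modelled as a centre point plus an
8-point ring at the rms radius (R/√2) of the uniformly filled source disk of
radius `S·NA/λ`, averaged incoherently; this matches the true source's
second moment while keeping 9 coherent renders per image.  Source tilts are
snapped to FFT-grid frequencies — an off-grid plane wave is not periodic on
the computational window and would leak power across the pupil edge,
producing spurious structure even for an empty specimen.  The quadrature is
adequate for qualitative contrast-versus-S behaviour; it is *not* accurate
enough for quantitative phase work at large defocus (see "sphere
experiment" below).

**Phantoms.**  Microspheres use the projected-chord thickness
`t(r) = 2√(R² − r²)` and phase `(2π/λ)Δn·t`; the refractive-index contrast
defaults to Δn = 0.1 since the synthetic pipeline controls both the
generation and the analysis side.  Random placement keeps each sphere about
one diameter clear of the field border: the Δz = 3 µm defocus halo
(~Δz·NA ≈ 2 µm wide) would otherwise fold back at the Neumann mirror
boundary and corrupt recovered heights (observed as ~+30 % outliers).
Cell-like phantoms are band-limited Gaussian noise, softly rectified, with a
2 µm correlation length and 2 rad peak phase.

**Camera and noise.**  Low-magnification acquisition renders at the native
grid with the low NA pupil and then block-averages by the magnification
ratio (camera pixel binning, not an ad-hoc blur).  Optional noise is Poisson
(10⁴ counts/pixel budget) plus additive Gaussian at 0.5 % of the mean; no
noise figure is inherent to the model, so both are configurable.

Grids default to 256×256 at 0.1625 µm/pixel (a 6.5 µm camera behind the
40× objective); presets cover 4×/0.1, 10×/0.25, 20×/0.4 and 40×/0.65 NA.

## TIE solver (`qpigan.tie`)

Teague's two-step factorisation with FFT inverse Laplacians.  Numerical
choices:

* **Neumann boundaries** by even mirror extension to a doubled grid
  (equivalent to a DCT-II cosine expansion but keeping a single FFT path);
  gradients and divergences are evaluated spectrally *on the extended grid*
  so even/odd symmetries of intermediate fields stay consistent.
* **Regularisation**: Tikhonov addend `ε = 1e-9·(2π/FOV)²` on the
  inverse-Laplacian symbol, DC bin hard-zeroed; the recovered phase is
  reported zero-mean (the constant is unobservable).
* **Intensity division** clipped at 1 % of the mean intensity; activation is
  logged.  Intensities are pre-normalised by the in-focus mean, making the
  result invariant to exposure scale.

## Sphere-height experiment (`qpigan.experiments`)

Fifty single-sphere fields (3 µm diameter, Δn 0.1) are rendered as
noise-free defocus stacks at Δz = 3 µm under the 40×/0.65 NA configuration,
inverted by TIE, and quantified as connected components above half the
robust (99th-percentile) peak, with each sphere's height taken as the
component's 95th-percentile phase minus the background median, converted by
`h = φλ/(2πΔn)`.  The percentile-based peak tolerates the edge ringing that
the finite Δz inevitably produces; the background reference makes the
statistic invariant to the solver's additive constant.

The experiment runs at **S = 0 (coherent illumination)**: the TIE closed
form inverts the coherent transport model, and the 9-point source quadrature
at 3 µm defocus otherwise superimposes a discretised source blur that biases
recovered heights low by ~17 % — a limitation of the desk-scale coherence
model, not of the solver.  Partially coherent rendering remains available
and is the default for dataset generation, mirroring practice (S ≈ 0.3 for
through-focus capture, S ≈ 0.6 for ordinary viewing).

Typical results (seeded): median height ≈ 2.96 µm, mean relative error
≈ 1–2 % against the 3 µm nominal diameter.

## Generator, discriminator, training (`qpigan.models`, `qpigan.train`)

The printed architecture fixes the Swin side's 4-pixel initial patch,
7-patch window and the 224 → 7×7 downsampling endpoint; everything else is
declared configuration, not inference:

* Swin branch: 4 stages, depths (2,2,2,2), heads (3,6,12,24), embedding 96
  doubling at each patch merging, all widths scaled by a factor (default
  0.5) for CPU-scale work; learned relative position bias per window;
  SW-MSA shift ⌊7/2⌋ = 3 with the nine-region border mask; pre-norm blocks
  with a 2-layer GELU MLP at expansion 4.
* CNN branch: 3-level stride-2 (kernel 4) encoder, transposed-convolution
  decoder with skip concatenation, instance normalisation, LeakyReLU.
* Fusion: each Swin stage output (pixel pitch 4·2^i) is nearest-neighbour
  upsampled ×4 and concatenated at the decoder level of pitch 2^i — one
  fusion per decoder level, which resolves the ambiguity of whether one or
  several levels receive attention features.
* No output activation; intensities and phases are linearly mapped to
  [−1, 1] using global training-set extrema that are stored in the
  checkpoint header (a single `.npz` whose JSON header carries the full
  architecture, so inference needs no external config).
* Discriminator: PatchGAN with kernel-4 convolutions; default plan
  (strides 2,2,2,1,1) has the classic 70-px receptive field and yields a
  30×30 score map on 256×256 input.  Depth is configurable (`n_layers`) so
  small toy images can be discriminated with a proportionally smaller
  receptive field.
* Objective: least-squares GAN.  The printed combined loss mixes the two
  players' terms; it is factorised in the standard minimisable form —
  discriminator `(D(real)−1)² + D(fake)²`, generator `(D(fake)−1)²` — with
  the cycle term `λ = 10` unchanged.  No identity loss is used.
* Optimiser: Adam (lr 2·10⁻⁴, β = (0.5, 0.999)), linear decay over the
  second half of training, batch size 2, 50-image replay buffer feeding the
  discriminators with historical fakes.  All randomness flows from one seed
  through named substreams; training is bit-reproducible on a device.

The networks run on a ~500-line reverse-mode autodiff core over numpy
(`qpigan.autograd`) providing exactly the needed primitives (broadcast
arithmetic, batched matmul, strided/transposed convolution, shape ops,
activations); gradients are verified against finite differences in the test
suite.

## Toy translation experiment

The desk-scale training check uses 24 blob phantoms per side on 32×32 grids
(20×/0.4 NA, S = 0.3, in-focus), a width-scale 0.125 model and ~200 steps.
Side B's phantoms are drawn independently of side A's, so no pair exists
even implicitly; the true phase of each side-A phantom is withheld for
scoring only.  At this scale the run demonstrates *direction*, not
convergence: the cycle loss falls by roughly half, and the generator's
outputs become structurally closer to the withheld phase than the raw
intensity inputs (whose in-focus contrast for a transparent object is
nearly nil).  Absolute SSIM values remain low — 200 steps of a GAN cannot
produce clean imagery — and nothing at this scale speaks to performance on
real micrographs, real noise, or real optical aberrations.

## Known limitations

* Scalar, aberration-free optics; no NA > 0.7, no vectorial effects.
* The 9-point condenser quadrature under-resolves the source disk at large
  defocus (quantified above).
* TIE at Δz = 3 µm is outside the strictly linear small-defocus regime for
  high-NA imaging; edge ringing is handled statistically, not removed.
* Synthetic data is registered by construction; no registration is
  implemented, and metric computation refuses images of unequal shape.
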
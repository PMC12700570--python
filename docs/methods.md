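# Methods

## The measurement being modeled

A microfluidic stream carries single cells along the flow axis y at
vy ≈ 0.16 m/s. A diffractive optical element shapes the illumination into a
needle beam — a Gaussian lateral profile exp(−2r²/w²) with w ≈ 3 µm held over
a ~40 µm depth of focus — which an acousto-optic deflector sweeps along x as
an ideal sawtooth at 200 kHz over 40 µm (scan speed vx = 8 m/s, period
T = 5 µs). Forward-scattered light is relayed past a spatial filter that
blocks the transmitted beam; a stack of micro-mirrors then routes light
originating from each of eight axial focal planes z_j (2.5 µm apart, centered
on z = 0) onto one channel of a PMT array. One transit of a cell therefore
writes its 3D scatter distribution into eight time series.

Two imperfections are central to the computation:

* **Beam blur.** Each sample convolves the object with the beam profile in
  both x (within a scan) and y (across scans).
* **Inter-plane crosstalk.** Scattered light from plane z_j can strike the
  mirror of channel i ≠ j. The coupling M_ij(y) is independent of x (the
  mirrors span the full scan length) and produces "ghost" copies of bright
  features on neighboring channels.

## Forward model

For scatterer c at (x_c, y_c, z_c) with strength I_c, channel i's sample at
time t accumulates

    M_ij(Δy) · exp(−2Δy²/w²) · I_c · exp(−2(x_c − x_n(t))²/w²) · a(z_c, z_j)

summed over planes j, where Δy is the offset between the scatterer and the
beam line along flow and a(·) is the axial assignment: nearest plane by
default, or a Gaussian of width `axial_psf_sigma` when a finite axial
response should spread a scatterer across adjacent planes. Intensities add
incoherently; there is no phase or speckle in the model.

Sample geometry is derived from integer sample indices (the digitizer is
synchronized to the sawtooth; the configuration validates that the sample
rate is an integer multiple of the scan rate). This avoids floating-point
jitter in `floor(t/T)` at scan boundaries, which otherwise corrupts the edge
columns of the demultiplexed image at the percent level.

`y_motion="exact"` (default) uses the instantaneous flow position at every
sample; `"frozen"` holds it fixed at the scan start, the approximation the
reconstruction inverts. Their difference is a channel-independent xy shear of
relative magnitude vy/vx (1/50 at the operating point, i.e. sub-pixel over a
cell diameter); the forward-error ratio between vy/vx = 1/50 and 1/500 is
measured at ≈ 10, confirming first-order scaling.

`build_dense_operator` materializes the same model as an explicit matrix of
impulse responses over a voxel grid. It is deliberately brute force: its only
role is to serve as an independent oracle for the FFT pipeline (agreement
≤ 1e−4 relative L2 on 12×12×4 grids; measured ~1e−7).

## Reconstruction

All Fourier operations use the ordinary-frequency convention
(kernel e^{−2πikx}), under which the transform of exp(−2x²/w²) is
w·√(π/2)·exp(−π²w²k²/2). The pipeline is:

1. **Demultiplex.** Sample k of scan n on channel i → pixel (row n, column
   k), with x from the in-scan beam position (pitch scan_range/samples_per_scan)
   and y = vy·nT (pitch 0.8 µm at defaults). Trailing partial scans are
   dropped, as are flyback-blanked columns when a dead-time fraction is set.
2. **Inverse beam filter along x.** Each row is multiplied in the frequency
   domain by G = H*/(|H|² + ε(max|H|² − |H|²)), which equals 1/H exactly at
   the passband peak (so the w → 0 limit is the identity) and rolls the
   exploding high-frequency gain off to a floor set by ε; a hard cap
   `max_gain` bounds the worst-case amplification. H is, by default, the DFT
   of the sampled beam kernel ("discrete"), which makes the inversion exact
   for the discretized model and coincides with the closed form
   exp(−π²w²k²/2) whenever the beam is adequately sampled (w ≳ 2·Δx); the
   closed form is available as `filter_form="gaussian"`.
3. **Axial unmixing per k_y.** U_ij(k_y) is the DFT (scaled by the y pitch,
   so it approximates the continuous transform) of M_ij(y)·exp(−2y²/w²)
   sampled on the padded row grid. For every (x, k_y) the N-channel system
   U f = V is solved by Tikhonov least squares
   (UᴴU + ridge·σ_max²·I) f = UᴴV, with σ_max the largest singular value of
   U over all k_y; `ridge=0` performs the bare solve and raises a
   singularity error naming the offending k_y if any U is numerically
   singular. Rows are zero-padded to the next power of two past the kernel
   support, which converts the circular FFT convolution into the linear one
   the forward model implements.
4. **Assemble.** Inverse y-FFT, planes ordered by ascending z_j, voxel sizes
   (plane_spacing, vy·T, scan_range/samples_per_scan). Negative values are
   retained internally and clipped only at threshold/rendering time, because
   clipping before peak metrics biases localization.

### Choosing ε and ridge

`epsilon = 1e−3` and `ridge = 1e−6` are robustness defaults for noisy or
tabulated inputs. For noiseless simulation studies the appropriate axial
setting is `ridge = 0` — the bare per-k_y inverse, exactly the reconstruction
formula — and the validation suites use it. The distinction matters
quantitatively: the Tikhonov term suppresses a transition band of y
frequencies where the Gaussian envelope of U crosses the ridge level, and for
point-like objects (flat y spectra) that suppression leaks a few percent of a
bright feature onto neighboring planes. With ridge = 0 the residual ghost
level on noiseless data is at numerical precision (~1e−10 of the true peak);
with the default ridge it is 2–3 % — still an order of magnitude below the
raw coupling, but worth knowing when interpreting ghost metrics.

## Phantoms

The generators reproduce the geometry of the system's validation objects; all
are seeded and byte-reproducible after serialization:

* **grid** — k point scatterers on each focal plane, uniformly placed under
  an in-plane minimum separation (default 5 µm) *and* a cross-plane lateral
  separation (default half of that): a scatterer hiding directly above
  another, closer laterally than the ~1.5 µm resolution, would make any
  recovery metric fail for reasons that say nothing about the pipeline.
  Intensities are all-equal or a per-plane pattern such as (1, 2, 3, 4, 5).
* **terrace** — a staircase of 35 × 8 µm² terraces with 2.5 µm steps; step
  edges scatter (points every 1.75 µm along the edge) and each terrace
  carries 1.5 × 1 × 1 µm³ bumps. When the step equals the plane spacing,
  terrace m coincides with detection plane m.
* **bead_shell** — a 25 µm sphere sampled by uniform surface points plus
  Poisson-distributed interior "pore" scatterers, mimicking porous hydrogel
  cell simulants.
* **cell** — uniform cytoplasmic scatterers (intensities 0.5–1.5) inside the
  cell sphere plus bright surface beads at `bead_intensity_ratio` × the
  internal mean (default 5, standing in for the polystyrene/cytoplasm
  refractive-index contrast; the ratio is a free parameter — no Mie
  computation is attempted).

What the phantoms do **not** emulate: coherent speckle, finite scatterer
size, refractive aberrations through the cell body, flow-position jitter, or
the instrument's real (ray-traced) crosstalk matrix — the tabulated
crosstalk mode accepts a measured M, but the shipped parametric modes are an
idealization. Passing round trips therefore demonstrate the correctness of
the computation, not the imaging performance on real cells.

## Metrics

* `detect_peaks`: 26-connected local maxima above a threshold fraction of the
  global maximum, greedy non-maximum suppression at a physical separation
  (defaults 0.5 and 1.5 µm — the threshold the validation figures imply; both
  surfaced as parameters). Peak x/y positions are refined by per-axis
  parabolic interpolation; z stays on the discrete detection plane.
* `integrated_amplitude`: in-plane window sum (default radius 2.5 µm) of the
  *unclipped* volume around a peak. The reconstructed spot of a point source
  is band-limited, so its voxel maximum varies ±10 % with the sub-voxel
  offset of the true position, while the window integral recovers the source
  strength to ~0.5 %; intensity-rank comparisons use it.
* `match_peaks`: greedy nearest-neighbor assignment in descending amplitude,
  no replacement — deterministic and adequate for ≤ 40-peak scenes.
* `estimate_diameter`: mean of the three bounding-box extents of the
  suprathreshold region, with the box edges refined by interpolating the
  threshold crossing on max-projection profiles (plain voxel counting
  quantizes at ± one pitch). Extent-based rather than volume-equivalent
  because shells reconstruct hollow.
* `crosstalk_suppression`: off-plane/on-plane response ratio before (raw
  channel images) versus after (reconstructed planes); requires a scene that
  leaves at least one plane empty.

## Problem sizes and determinism

The validation suites run at the instrument's native sampling — 64 samples
per 40 µm scan, 0.8 µm row pitch, 8 channels — on scenes of 16–40 point
scatterers or ~500-point shells; a full simulate-reconstruct-score round trip
takes well under a second, and the whole test suite a few seconds. The
dense-operator oracle uses a 4-channel, 16-sample configuration with a 2 µm
row pitch so the operator stays small and well conditioned. Every stochastic
step (phantom placement, noise) flows from explicit integer seeds;
noiseless runs are bit-reproducible, including the HDF5 container.

## Known limitations

* The y-rescaling in `compensate_flow_speed` restores the aspect ratio of
  objects imaged at off-nominal flow speeds but is a linear-resampling
  approximation of a full speed calibration.
* The axial response is either nearest-plane or a parametric Gaussian; the
  instrument's true axial PSF (and its angular collection behavior) is not
  derived here.
* The crosstalk magnitude of the real mirror array is unknown to this
  package; the nearest-neighbor ε default (0.2 in the examples) is a test
  condition, not a measurement, and y-dependence of M is supported only
  through the tabulated mode.
* Reconstruction is single-pass linear filtering; no iterative or
  positivity-constrained variants are provided.
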
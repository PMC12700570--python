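# fsc3d — 3D forward-scattering imaging flow cytometry, simulated end to end

Label-free 3D imaging of single cells in flow: a needle-shaped Gaussian laser
beam (waist w ≈ 3 µm, depth of focus ≈ 40 µm) is swept along **x** by an
acousto-optic deflector at 200 kHz while the cell is carried along **y** at
vy ≈ 0.16 m/s by a microfluidic sheath flow. A micro-mirror array routes the
forward-scattered (dark-field) light from eight axial focal planes z_j
(spacing 2.5 µm) onto an eight-channel PMT array, so a single transit encodes
a full 3D scatter volume in eight time series — at ~400 cells/s.

`fsc3d` implements both directions of that measurement for anyone who wants
to study, validate or extend the computational pipeline without the
instrument:

* a **forward simulator** that turns a 3D scatter scene into the
  multi-channel PMT readout, including inter-plane crosstalk and optional
  detector noise, and
* the **spatiotemporal reconstruction** that demultiplexes the time series
  into per-plane images, deconvolves the beam profile, unmixes the crosstalk
  and assembles the volumetric image,

plus phantom generators (point grids, terraced micro-structures, porous-bead
simulants, cells with surface beads) and quantitative fidelity metrics.

## Signal model

With the beam at sawtooth position x_n(t) = vx·(t − T/2 − nT) and the object
at flow position vy·t, channel *i* records

    P_i(t) = Σ_j ∬ dx dy  M_ij(y) · exp(−2y²/w²) · f(x, vy·t − y, z_j)
                         · exp(−2(x − x_n(t))²/w²)

where f is the scatter intensity distribution and M_ij(y) is the crosstalk
matrix coupling object plane z_j into channel i (identity when the
micro-mirrors separate planes perfectly). Because vx ≫ vy the object's y
position is frozen within one scan, so sample k of scan n maps to pixel
(x_k, vy·nT) — an image grid with pixels 0.625 × 0.8 µm² at the default
operating point.

The reconstruction inverts the model in the Fourier domain (ordinary
frequency convention):

1. per row, multiply the x-spectrum by a regularized reciprocal of the beam
   transfer function H(k_x) ∝ exp(−π²w²k_x²/2) (Wiener form);
2. per y-frequency k_y, solve the N×N linear system with matrix
   U_ij(k_y) = F_y{M_ij(y)·exp(−2y²/w²)} by Tikhonov-regularized least
   squares (the bare inverse for noiseless data);
3. inverse-transform along k_y and stack the planes in ascending z_j.

## Worked example

Simulate the classic validation scene — two point scatterers on each of the
eight focal planes, with 20 % nearest-neighbor crosstalk — and reconstruct it:

```sh
fsc3d phantom grid --k 2 --planes 8 --xy-extent 20 --seed 7 --out phantom
fsc3d simulate --scene phantom/scene.csv \
               --crosstalk nearest_neighbor --epsilon 0.2 --out signal
fsc3d reconstruct --record signal/record.h5 --resize 200 200 100 \
                  --peaks --out volume
fsc3d evaluate --record signal/record.h5 --truth phantom/scene.csv --out report
```

The log echoes the derived operating point and the outcome:

```
INFO fsc3d: wrote 16 scatterers to phantom/scene.csv
INFO fsc3d: vx = 8 m/s, T = 5 us, 64 samples/scan, 55 scans
INFO fsc3d: resampled volume to (100, 200, 200) (z, y, x)
INFO fsc3d: detected 16 peaks
```

and `report/report.json` contains

```json
{
  "n_truth": 16, "n_found": 16, "n_matched": 16,
  "recall": 1.0, "precision": 1.0,
  "mean_distance_um": 0.3770569548709246,
  "max_distance_um": 0.5839592547888939
}
```

— every scatterer is recovered on its correct focal plane, localized to well
under one pixel, with the crosstalk ghosts removed by the axial unmixing.
`volume/volume.ome.tiff` holds the reconstruction resampled to
200 × 200 × 100 voxels with physical voxel sizes in the OME metadata, and
`volume/peaks.csv` the detected peak table.

The same workflow is available as a library (`fsc3d.simulate`,
`fsc3d.reconstruct_volume`, `fsc3d.detect_peaks`, …); see `docs/methods.md`
for the model details and parameter guidance.

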
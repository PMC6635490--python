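# Methods

## Scope and model overview

deepdose estimates voxel-level absorbed dose (Gy) and dose rate (Gy/s) from
co-registered activity (PET-like, Bq/mL) and CT-number (HU) volumes for a
positron emitter (⁶⁸Ga by default), by three routes: direct Monte-Carlo
transport on the patient-specific density grid (the ground truth), voxel
S-value kernel convolution in water (the fast analytic baseline), and a
patch-based 3-D U-net regression trained against the Monte-Carlo maps.  All
experiments run on synthetic phantoms; the package's claims are therefore
about method consistency and learning behaviour under controlled conditions,
not about clinical accuracy.

## Synthetic phantoms

A phantom is a list of ellipsoid/cuboid organs on a voxel grid (default
test grid 64×64×32 or smaller at the PET voxel size 2.67×2.67×5 mm³), each
with a material tag, an initial activity concentration and an effective
clearance half-time.  Materials come from a fixed five-class table
(air −1000 HU / 0.00121 g/cm³, lung −740 / 0.26, adipose −98 / 0.95, soft
tissue 0 / 1.000, bone 1200 / 1.85).  HU→density conversion is
piecewise-linear through exactly these breakpoints (monotone, clamped to air
below −1000 HU, linearly extrapolated above bone), so CT and density volumes
are mutually consistent and auditable.  Voxels covered by several organs
belong to the last-listed one; there are no partial-volume fractions,
matching how voxelised phantoms are imported by Monte-Carlo toolkits.

Dynamic series multiply each organ's concentration by 2^(−t/T_eff) with the
organ's own effective half-time; background activity decays with the
physical ⁶⁸Ga half-life (67.71 min).  The default imaging schedule is eight
frames at 1, 4, 7, 10, 15, 30, 46 and 62 min.

What the phantoms deliberately do *not* model: anatomically realistic
shapes, PET image formation (noise, resolution, bladder artifacts), partial
volume effects, or imperfect organ segmentation — labels are exact by
construction.  Passing tests therefore demonstrate algorithmic correctness
and the density-dependence physics, not robustness to image degradation.

## Monte-Carlo engine

Per decay: a positron is emitted with probability 0.889 and its mean kinetic
energy (0.836 MeV) is deposited in the source voxel — the ⁶⁸Ga positron
range (~mm) is below the voxel size, so local deposition is the engine's
chief documented simplification.  Two back-to-back 0.511 MeV photons follow
(plus a 1.077 MeV gamma at 3.2 % yield), transported by Woodcock tracking
across the density grid with density-scaled *water* coefficients: Compton
scattering sampled from the Klein–Nishina distribution
(Butcher–Messel composition-rejection), a photoelectric power-law fit
anchored to water at 10 keV, no coherent scattering, and a 10 keV cutoff
with local deposition.  Recoil-electron energy deposits at the interaction
voxel.  Energy arriving in a voxel with zero density is reassigned to the
most recent massive voxel along the track.  Nuclide data are overridable via
`DecayScheme`.

Tallies are split into 10 batches (configurable); per-voxel relative
uncertainty is the batch standard error over the mean.  The engine is
strictly linear in activity and bit-deterministic for a fixed seed.
Verified properties: deposited/emitted energy = 0.9996 at 10⁶ histories for
a point source in a ~19-mean-free-path water cube (the deficit is real
photon escape); uncertainty scales as 1/√N; agreement with the water kernel
(below) within ~2 % mean voxel difference in uniform water, most of which is
MC noise.

The published workflow this engine stands in for ran full Geant4
electromagnetic physics on a compute cluster; this engine trades elemental
cross-sections and electron transport for desk-scale speed with the accuracy
envelope stated above, and makes no claim of event-count parity with GATE.

## Voxel S-value kernel

The kernel is generated by running the same engine with a single-voxel
source at the centre of a uniform water box (kernel extent + 2 voxels
margin) and normalising to Gy per MBq·s.  Kernel dims default to 49×49×25 —
the odd-sized analogue of the 48×48×24 training patch, itself chosen to
cover the ⁶⁸Ga dose range; desk-scale tests use 33×33×17, which fully covers
a 32×32×16 phantom from its centre.  A warning fires if the kernel captures
< 95 % of the non-escaping energy.  Convolution is zero-padded (no activity
outside the imaged volume), computed directly below 20,000 output voxels and
by FFT above; both routes agree with the explicit double sum to better than
1e-10 relative, which the acceptance suite re-verifies.  Dose-rate maps for
a single frame read the same equation per unit time (Ã per second).

The kernel assumes water everywhere.  In lung (ρ = 0.26) the dominant local
(positron) term is under-dosed by roughly the density ratio, giving ~70 %
voxel errors — the directional failure the network is meant to fix.  A
multi-material kernel set is out of scope.

## Patch pipeline

Static volumes are divided into overlapping 48×48×24 patches on a regular
(7, 7, 5)-voxel offset grid (30·30·29 = 26,100 candidate positions on a
256×256×165 grid); patches with less than 1/8 of their voxels inside the
body mask are excluded, and a per-image cap (5,000) is applied by seeded
uniform subsampling, reproducing the 8×8×5,000 = 320,000-patch bookkeeping
of the full-scale protocol.  The body mask is HU > −500, largest connected
component, with interior cavities (lungs) filled.  Coordinates are 0-based,
inclusive-start/exclusive-end, ordered lexicographically.  Desk-scale tests
use 16×16×8 patches at (4, 4, 2) offsets — same machinery, smaller numbers.

At inference, patches are laid on a half-patch stride with extra flush
patches at the far boundaries (the training offsets are a data-generation
choice; inference needs full coverage), and overlapping predictions are
averaged with uniform weights; a coverage-count map and report are emitted.

## Network

A standard 3-D U-net: contracting levels of two 3×3×3 convolutions each
followed by batch normalisation and ReLU, 2×2×2 max pooling between levels,
feature maps doubling from 14 in the first layer (full-scale profile);
expanding path of stride-2 transposed convolutions, skip concatenation and
two convolutions with ReLU only — batch normalisation is restricted to the
contracting path, a literal reading of the architecture description, and is
configurable.  Depth defaults to 4 levels (axial 24→12→6→3; the 24-voxel
patch caps the pooling count).  Final layer is a 1×1×1 convolution to one
channel.  Inputs are scaled by persisted global constants (PET by its
99.9th percentile, CT by 1000); dose targets by their 99.9th percentile;
the constants travel with the saved model.

Training minimises the L1 norm with Adam.  The full-scale protocol values
(batch 150, 7 epochs, five-fold cross-validation with 8 train / 2 test
subjects) are retained in the "paper" profile; the desk profile uses batch
4–16 and a width-4, depth-3 net.  The learning rate is not part of the
published protocol; the package defaults to 1e-3 with the desk benchmark
using 3e-3 under a linear decay to zero, which measurably stabilises
small-batch runs.  Weight init is He-normal, seeded; training is
bit-deterministic for fixed seeds.

The network is implemented directly on numpy (im2col-style convolutions via
`sliding_window_view` + einsum, hand-written backward passes, Adam), which
keeps the package free of deep-learning framework dependencies and makes
every gradient unit-testable against finite differences.  It is a CPU-scale
implementation: the full 320,000-patch protocol is out of its intended
range.

## Dose integration and statistics

Dose-rate frames integrate per voxel as: trapezoid from the first to the
last frame time; the rate held constant at its first-frame value over
[0, t₁) (a "zero" head model is selectable); and an analytic exponential
tail R_last/λ after the last frame, with λ defaulting to physical ⁶⁸Ga decay
— the conservative standard when late kinetics are unknown.  On exponential
rates sampled at the 8-point schedule this reproduces r₀/λ to ~0.05 %.

Organ doses are energy-weighted means (Σ dose·voxel mass / Σ mass) over the
label; the reference-mass correction multiplies by patient-organ mass over
the ORNL/Cristy–Eckerman stylized-phantom mass (packaged, editable).  The
correction direction is one documented reading — the published description
does not print a formula — and is swappable.

Voxel errors follow the benchmark formula |method − MC| / MC × 100 averaged
over mask voxels, with voxels below 0.1 % of the reference maximum excluded
(the formula is unstable at near-zero dose; the floor is configurable and
reported).  The reference is always the Monte-Carlo map; the metric is
deliberately asymmetric.  Organ-level differences average per-organ over
subjects, with cross-organ row averages reported both with and without a
named outlier organ (the published table excludes the pancreas, whose
near-zero reference dose makes the organ-based method's error explode).
Paired t-tests are two-sided with Bonferroni-adjusted α = 0.05/m; identical
samples return a "degenerate" status rather than a fabricated p-value.

## Scaled-down study sizes

The desk-scale experiments are sized for a single CPU: 32×32×16 thorax
phantoms (box torso, interior lung block of ~12 % body volume, one hot
organ; uptakes and positions jittered per phantom), 5–10 × 10⁶ Monte-Carlo
histories per static frame (≈ 3–5 % voxel noise), a 33×33×17 kernel at
3–4 × 10⁶ histories, 500 training patches of 16×16×8 from four phantoms, and
a width-4 depth-3 U-net trained 7 epochs.  The held-out comparison in
`learning_benchmark` averages the predictions of three independently
initialised training runs (a deterministic small ensemble, reducing the
run-to-run variance a single tiny network exhibits) and evaluates on a
fifth, structurally similar but unseen phantom.  Under these conditions the
network's held-out whole-body voxel error lands below the water-kernel
baseline, and its lung error about an order of magnitude below — the
direction, not the magnitude, of the full-scale published comparison.

## Known limitations

- No electron transport, elemental composition, or coherent scattering in
  the MC engine; photoelectric below ~30 keV is a power-law approximation.
- Local positron deposition ignores the few-mm ⁶⁸Ga positron range.
- The network profile that reproduces the published training scale exists
  as configuration only; numpy throughput makes it impractical.
- Phantoms are geometric; nothing here measures robustness to PET/CT
  artifacts or segmentation error.
- The pancreas-style near-zero-dose failure mode of organ-based dosimetry
  is represented only through the packaged published comparator numbers,
  since organ-based (MIRD phantom) dosimetry itself is out of scope.
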
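# Methods

This note documents the kinetic model, the imaging model, the measurement
procedures and the numerical choices behind `vactraffic`, in the spirit of
the methods documentation of simulation packages: what is modeled, what is
deliberately not, and what the validation does and does not show.

## Compartment-level kinetic model

A simulated cell contains maturing Golgi cisternae, one vacuole, and one or
more PVE (prevacuolar endosome) compartments attached to the vacuole
surface (each PVE centre lies within one PVE radius of the surface; the
compartments never disappear, mirroring the persistence of Vps8-marked
structures in live cells).

**Cisternal maturation.** Each cisterna has a birth time, a lifetime `L`
(default 180 s) and a transition midpoint `m` at fraction `φ` (default
0.5) of its life. Marker channels are logistic in time with time constant
`τ = L/12`: the early marker decays as `σ((m−t)/τ)`, the late marker rises
as `σ((t−m)/τ)` and departs as `σ((t_d−t)/τ)` at the end of life. The GGA
adaptor channel follows the late marker (they arrive together); the AP-1
channel is the same pulse shifted by `adaptor_offset_arrival` (default
30 s) and `adaptor_offset_departure` (default 12 s), the middle of the
ranges reported for live cells (~20–40 s and ~10–15 s). In `gga_null` mode
`τ` is doubled, emulating the abnormally shallow marker transitions of
GGA-deficient cells.

**Cargo in cisternae.** Constant until the midpoint; afterwards it decays
exponentially at `cargo_exit_rate` (default 0.015 s⁻¹, giving ~0.5 of the
plateau 45 s past the midpoint) in `wildtype` and `apl4_null` modes. In
`vps10_null` mode the cargo instead rises transiently by
`cargo_overshoot` (default 1.3, a Gaussian bump after the midpoint
emulating AP-1-dependent recycling from older cisternae) and persists; in
`gga_null` mode the exit rate is forced to zero and the cargo persists
through late-marker departure. Cargo leaving cisternae is credited equally
to the PVE compartments (to the vacuole if there are none).

**PVE → vacuole transfer.** Each PVE starts loaded with
`pve_initial_cargo` (100 a.u.). A compartment drawn quiescent (probability
`quiescent_prob`, default 0.2) accepts cargo but never delivers; active
compartments may additionally carry an onset delay before delivering
(used for delivery cohorts). Active compartments lose cargo continuously
at `pve_leak_rate` (default 5×10⁻⁴ s⁻¹) and in instantaneous bursts at
Poisson times with rate `burst_rate` (default 1/300 s⁻¹, one event per
5 min) and fractions drawn from a normal (mean 0.375, sd 0.12) truncated
to (0.16, 0.95): events below the 15% detection threshold would be
invisible to the burst statistic, and near-total transfers are observed.
With these defaults the gradual leak accounts for roughly a quarter of the
total transfer, so bursts carry ~75% of it. Every loss is credited to the
vacuole within the same frame; bursts execute between consecutive frames,
matching transfers that complete within a single stack interval.
Consequently, bleach-free noiseless simulations conserve summed cargo to
floating-point precision — except in `vps10_null` mode, whose overshoot
deliberately injects recycled signal from outside the tracked ledger; the
conservation suite therefore randomizes over the other modes.

**Photobleaching.** `apply_photobleach` emulates the pre-acquisition
bleach of everything except the PVE compartments: at the bleach frame the
vacuole's cargo pool is reduced by the bleach efficiency and stays
reduced, while later arrivals are unbleached (`V′(t) = V(t) − e·V(k)`);
punctate non-PVE compartments are scaled by `1−e`. Cargo released by a
bleached cisterna after the bleach is still credited at schedule
brightness — a corner that does not arise in the emulated protocols, which
bleach only once the Golgi pool is negligible.

**Delivery cohorts.** `simulate_delivery_cohort` draws a per-cell onset
delay from a two-component uniform mixture (default: 65% of cells in
4–14 min, 35% in 16–29 min, so that 35% of cells start delivering later
than 15 min — the observed slow tail), simulates each cell with preloaded
PVEs, and applies a complete vacuole bleach at frame 0. In `vps10_null`
mode the PVE and vacuole pools start empty (without the receptor the cargo
is secreted instead), so the vacuolar curve stays at zero.

## Imaging model

Punctate compartments are rendered as anisotropic 3-D Gaussians with
`σ = sqrt(σ_PSF² + (r/2)²)`; kernels are normalized so that the integrated
intensity equals `photon_gain × true_signal` (linearity is exact to the
patch truncation, <1%). The vacuole membrane is a Gaussian-blurred
spherical shell (radius default 1.2 µm, a config field — typical for yeast
vacuoles) and luminal cargo a PSF-smoothed filled sphere, both
mass-normalized. The vacuole's total membrane signal is
`marker_amplitude × vacuole_marker_scale` (default ×20): an organelle with
~20× the membrane area of a punctum carries proportionally more marker,
and this keeps the shell detectable above the noise floor. Noise is
Poisson about the noiseless image plus a flat background (default 2
counts), with additive Gaussian read noise, clipped at zero. A punctum
whose ±3σ support leaves the field raises a geometry error. Acquisition
presets mirror the experimental designs: 2 s stacks over ≥90 s
(maturation), 60 s stacks over 60 min (delivery), 5 s stacks over 10 min
(bursts); 60–80 nm pixels, 0.25–0.30 µm Z-steps, 20–30 sections.

Movies are written as OME-TIFF (axes TCZYX, uint16) with the channel-role
map stored as OME channel names and the voxel/time geometry in the OME
pixel attributes; ground truth travels in a JSON sidecar. Reading a file
without the role map is a hard error.

## Quantification

Structures are segmented per frame from a marker channel: Gaussian
smoothing (1 XY voxel, Z-scaled), thresholding, 26-connected components
of at least `min_voxels` (default 10) voxels. Two threshold policies are
exposed: Otsu (default; appropriate when the foreground occupies a
non-negligible volume fraction, e.g. the vacuole shell, or for noise-free
images) and `mean + k·sd` (used by the pipeline with k = 4 for punctate
channels in noisy movies, where Otsu's bimodality assumption fails).
Vacuole-membrane masks are morphologically closed and filled so they
include the lumen, and eroded by one voxel before measuring luminal
cargo; punctate masks are dilated (2 voxels) to capture the blurred spot
periphery. When measuring cargo inside the vacuole, dilated PVE masks are
excluded first, so a vacuole-attached PVE does not contaminate the
luminal measurement.

Tracking is greedy nearest-centroid linking with a maximum per-frame
displacement (default 0.5 µm), ties broken by distance, then overlap,
then canonical (centroid-sorted) label — deterministic and independent of
input order. Measurement is the in-mask sum minus `n_voxels ×` the median
of the channel outside all masks of the frame, floored at zero; the
median background makes every trace scale-equivariant. Maturing cisternae
are tracked on a synthetic channel equal to early + late marker, which
stays approximately constant through the transition.

Because a threshold mask captures only part of a blurred structure's
integrated intensity, measured traces are proportional to the true
per-compartment signal rather than equal to it; all downstream analyses
(top-3 and endpoint normalization, midpoint crossing, burst fractions,
5%-of-final appearance) are scale-invariant by construction, and
trace-fidelity checks compare peak-normalized shapes (RMS ≤ 5% of the
trace maximum on noise-free movies).

The "detectable cargo" score (fraction of compartments whose in-mask mean
exceeds the background mean + k·sd, default k = 3) is an automated
stand-in for the manual scoring used on real movies; the threshold has no
experimental calibration and results that depend on it should be read as
relative, not absolute.

## Trace analyses

* `normalize_top3` divides by the mean of the three highest values (robust
  peak normalization for noisy marker traces); `normalize_endpoint6`
  anchors to the mean of the first six (cargo, early marker) or last six
  (late marker) samples of the event window.
* The transition midpoint is the first upward crossing of the
  peak-normalized late trace over the early trace, linearly interpolated;
  among multiple crossings the one nearest the late trace's half-maximum
  time wins. The definition is parameter-free and amplitude-robust. On
  logistic traces the peak normalization biases the estimate by under a
  second at default slopes (up to ~4 s for the shallow `gga_null` slopes).
* Events are aligned at their midpoints on a 2 s grid (nearest grid point,
  ties toward earlier time) and averaged; grid points with fewer than 50%
  of events contributing are dropped, and events whose traces do not cover
  [−40 s, +45 s] around the midpoint are excluded (the event-window
  convention of 90 s acquisitions).
* Adaptor arrival/departure are sustained half-maximum crossings (≥2
  consecutive frames above the level, linear interpolation); offsets are
  other − reference. On asymmetric logistic pulses the estimator carries
  an intrinsic bias below ~3 s for offsets up to 40 s, within the ±4 s
  recovery target; traces never crossing the level report missing values.
* Delivery: `final_value` is the mean of the last three frames (robust to
  single-frame noise); appearance is the first frame reaching 5% of it;
  cells with final value under 3× a configurable noise floor are left
  unscored rather than scored at spurious times.
* Bursts: the remaining series takes the frame nearest each 10 s boundary
  (ties earlier). Interval fractions floor negative drops at zero;
  a burst requires the fraction > 0.15 **and** the compartment to hold
  more than 2% of its initial cargo (a guard against noise calls on
  nearly empty compartments, a regime the original rule does not
  address). Consecutive qualifying intervals count as separate bursts
  (the rule scores intervals, not merged episodes). The total fraction
  transferred in bursts is relative to the total net transfer by default
  (`relative_to="initial"` is available). Active compartments are those
  whose net transfer exceeds 10% of initial cargo. An optional vacuole
  cross-check flags bursts whose PVE decrease is not matched by at least
  half as large a vacuole increase.

## Validation scope and problem sizes

All stochastic tests are seeded. Recovery tests run at reduced problem
sizes chosen for fast, deterministic CI-style runs: 40×40×12 to
64×64×14 voxel fields for rendered movies, 50 ten-minute movies for burst
recovery, 200 events for adaptor timing, 100 cells for the delivery
population, 25 events per mode for the aligned averages — sizes at which
the binomial/Poisson error bands in the assertions are meaningful. The
acceptance script uses the same sizes and finishes in well under a minute.

Passing these tests shows that the implemented statistics recover the
generator's truth under the generator's assumptions (isolated cells,
marker-faithful masks, flat background, Gaussian PSF, Poisson noise). They
do not certify performance on real movies, which add deconvolution
artifacts, cell-to-cell expression variability, sub-resolution compartment
clusters, focus drift and photobleaching during acquisition — none of
which are modeled beyond the flat background and the explicit
pre-acquisition bleach step.

## Known limitations

* No optical sectioning physics beyond the Gaussian PSF; no cytoplasmic
  autofluorescence structure beyond a flat offset.
* The simulator treats bursts as true transfers; whether some observed
  bursts in real data are artifacts of clustered full fusion is outside
  its scope.
* Compartment positions are static; linking is validated on constructed
  moving spots but the simulator does not exercise large motilities.
* Absolute brightness and background are free parameters; nothing in the
  analyses depends on absolute scale.
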
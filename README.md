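# vactraffic

Synthetic 4D confocal movies and kinetic quantification of yeast
Golgi-to-vacuole cargo traffic.

In budding yeast, a biosynthetic vacuolar cargo (a CPY-type cargo carrying
the QRPL sorting signal) travels from the ER through maturing Golgi
cisternae to prevacuolar endosome (PVE) compartments, and from there to the
vacuole. Live-cell 4D microscopy of this pathway raises quantification
problems that this package solves in a reproducible, testable form:

* **When does the cargo leave the Golgi?** Per-cisterna fluorescence traces
  of an early marker (Vrg4), a late marker (Sec7) and the cargo are
  normalized, aligned at the early-to-late transition midpoint and
  averaged. In wild-type kinetics the cargo starts to decline at the
  midpoint, when the GGA adaptors arrive; without GGAs it persists; without
  the Vps10 receptor it overshoots and persists.
* **How does cargo reach the vacuole?** PVE compartments are long-lived and
  transfer content by kiss-and-run fusion: a gradual leak punctuated by
  discrete bursts. The burst statistic scans the remaining PVE cargo
  $R_i$ at 10 s intervals and calls a burst whenever
  $f_i = \max(0, R_{i-1}-R_i)/R_{i-1} > 0.15$.
* **How fast is whole-cell delivery?** Per-cell vacuolar accumulation
  curves (cargo measured inside a Vph1-defined vacuole mask, 60 s stacks
  for an hour), first-appearance scoring at 5% of the final value, and
  population mean ± SEM.

Because the original movies are not deposited, the package pairs these
analyses with a forward simulator that emulates the acquisitions
(60–80 nm pixels, 0.25–0.30 µm Z-steps, 20–30 sections, Gaussian PSF,
Poisson photon noise, pre-acquisition photobleach) on top of a
compartment-level kinetic model with exact ground truth, so every analysis
can be validated by parameter recovery.

## Model summary

Per cisterna with transition midpoint $m$ and lifetime $L$: the early
marker decays as a logistic $\sigma((m-t)/\tau)$, the late marker rises as
$\sigma((t-m)/\tau)$ and departs at $t_d = m + (1-\phi)L$; cargo is
constant until $m$, then $C(t) = C_0 e^{-k(t-m)}$ (wild type). The AP-1
channel repeats the late-marker curve shifted by configurable arrival and
departure offsets. Each active PVE compartment loses cargo continuously at
rate $\lambda$ plus instantaneous bursts at Poisson times (default rate
1/300 s⁻¹) with truncated-normal fractions (mean 0.375, support
0.16–0.95); everything a PVE loses is credited to the vacuole in the same
frame, so noiseless simulations conserve total cargo exactly.

## Worked example

Simulate one 10-minute burst movie at the study conditions and run the
kiss-and-run statistic on the PVE cargo trace:

```python
from vactraffic import (KineticConfig, burst_optics, simulate_timeline,
                        remaining_series, detect_bursts, summarize_bursts)
from vactraffic import roles as R

kinetics = KineticConfig(quiescent_prob=0.0)   # study defaults otherwise
optics = burst_optics()                        # 5 s stacks, 10 min
timeline, truth = simulate_timeline(kinetics, optics,
                                    n_cisternae=0, n_pve=1, seed=11)
trace = timeline.trace("pve0", R.CARGO)
times, remaining = remaining_series(trace, interval=10.0)
table = detect_bursts(times, remaining, threshold=0.15)
summary = summarize_bursts(table)
print(f"bursts detected: {summary.n_bursts} "
      f"(scheduled: {len(truth.burst_schedule['pve0'])})")
print(f"frequency: {summary.frequency_per_min:.3f} per min")
print(f"mean fraction per burst: {summary.mean_fraction_per_burst:.2f}")
print(f"fraction of transfer in bursts: "
      f"{summary.total_fraction_in_bursts:.2f}")
```

Output:

```
bursts detected: 1 (scheduled: 1)
frequency: 0.100 per min
mean fraction per burst: 0.45
fraction of transfer in bursts: 0.75
```

One scheduled kiss-and-run event was recovered exactly: 45% of the
remaining cargo moved to the vacuole in that 10 s interval, and bursts
accounted for 75% of the total transfer in this movie (the rest was the
gradual leak).

The full rendered pipeline (simulate → OME-TIFF → segment → track →
measure → analyze) runs from a YAML config:

```sh
vactraffic all --config examples/bursts_demo.yaml --seed 5 --out out/
```

which writes the movie (`movie.ome.tif` with the channel-role map in the
OME metadata and the ground truth in a JSON sidecar), tidy trace CSVs, the
burst table/summary CSVs and plots. Subcommands `simulate`, `quantify`,
`maturation`, `delivery` and `bursts` run the individual stages.

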
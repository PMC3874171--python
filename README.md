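# nucdyn

Stochastic simulation of nucleosome positioning and kinetics near
transcription-start-site (TSS) barriers.

## The problem

Nucleosome-sequencing experiments show oscillatory nucleosome occupancy
downstream of the nucleosome-free region (NFR) at most TSSs. Two mechanisms
compete to explain it: *statistical positioning* — pure hard-core packing of
nucleosomes against a barrier — and sequence-dependent histone–DNA binding
energies. Because spontaneous (thermal) nucleosome eviction and sliding are
astronomically slow, the question is inherently kinetic: which patterns can
actually form within a cell cycle, and only with the help of ATP-dependent
chromatin remodeling?

`nucdyn` is a tool for exploring exactly this. It implements:

* a **continuous-time Monte Carlo (Gillespie) simulator** of nucleosomes as
  147-bp hard rods on a DNA lattice, with three elementary moves —
  adsorption at rate `k_on` per eligible start position, removal of the
  nucleosome starting at `i` at rate `k_off(i) = k0_off · exp(V_i + V_a)`,
  and ATP-driven slide-to-contact at rate `k_slide` per nucleosome.
  `V_i` (in k_BT) is the sequence-dependent binding energy of a nucleosome
  starting at base pair `i`; the thermal limit `V_a = 0` satisfies the
  Boltzmann condition `k_on / k_off(i) = exp(−V_i)`, while `V_a > 0` models
  the chemical energy coupled into active eviction;
* **barrier models** for the NFR: a hard barrier (no binding, no sliding
  through), a soft barrier (linear ramp `V(j) = −(13/150)·j` k_BT over
  `j ∈ [−150, −1]`), and a firmly positioned immobile nucleosome;
* **exact oracles**: the grand-canonical equilibrium coverage of hard rods
  in an arbitrary external potential (Percus-style transfer recursions,
  log-stabilized, O(N)), brute-force configuration enumeration, and a
  master-equation integrator for small lattices;
* **kinetic statistics**: replica-averaged occupancy profiles, the
  barrier-vs-no-barrier deviation length `l0`, the relaxation time
  `τ_relax` after barrier insertion, per-site exposure statistics
  (`N_e` events, `t_e` mean duration for 10-bp sites), and paired
  sensitivity scans of density vs exposure kinetics to potential shifts;
* a **synthetic gene-potential generator** (Gaussian field with exponential
  autocovariance plus a weak ~10-bp periodicity) standing in for
  sequence-model-derived binding-energy tracks, so everything runs without
  external data.

## Worked example

```python
import numpy as np
from nucdyn import (BarrierSpec, KineticParams, calibrate_activity,
                    occupancy_profile, oscillation_amplitude,
                    percus_occupancy, run_ensemble, uniform_potential)

# homogeneous DNA, V = -7 k_BT, TSS at bp 400, hard 150-bp barrier upstream
track = uniform_potential(2400, -7.0, tss_offset=400)
barrier = BarrierSpec(kind="hard")          # j in [-150, -1]
params = KineticParams()                    # k_on = 0.06/s, k_slide = 0.1/s

# calibrate the active eviction shift V_a to steady-state coverage 0.85
shift = calibrate_activity(uniform_potential(10_000, -7.0), params,
                           target_density=0.85, base_seed=0)
print(f"V_a = {shift:.2f} k_BT")

active = run_ensemble(track, params.with_shift(shift), barrier,
                      t_end=3600.0, snapshot_times=[3600.0],
                      n_replicas=500, base_seed=1, record_events=False)
profile = occupancy_profile(active, 3600.0)
print(f"coverage at TSS+75 bp: {profile.relative_slice(75, 76)[0]:.2f}")
print(f"oscillation amplitude j in [200,1500]: "
      f"{oscillation_amplitude(profile):.3f}")

thermal = KineticParams(k_slide=0.0, active_shift=0.0)
therm = run_ensemble(track, thermal, barrier, t_end=3600.0,
                     snapshot_times=[3600.0], n_replicas=500, base_seed=2,
                     record_events=False)
print(f"thermal amplitude: "
      f"{oscillation_amplitude(occupancy_profile(therm, 3600.0)):.3f}")
```

Output:

```
V_a = 6.02 k_BT
coverage at TSS+75 bp: 0.88
oscillation amplitude j in [200,1500]: 0.026
thermal amplitude: 0.027
```

At one hour the active run has built statistical-positioning oscillations:
the first positioned nucleosome sits directly at the barrier and occupancy
swings between ~0.70 and ~0.88 with a ~160-bp period out to several hundred
bp. The two amplitudes look similar here only because 500 replicas leave
~0.02 of binomial sampling noise in both profiles: scaling the ensembles up
(2,000 active / 20,000 thermal replicas, as the test suite does) resolves a
genuine active amplitude of ~0.030 against a thermal one of ~0.013, and the
thermal structure is entirely the shadow of the single positioned nucleosome
adjacent to the barrier — the thermal deposit is otherwise a jammed,
unpositioned film.

A command-line surface wraps the same operations
(`nucdyn make-tracks | simulate | analyze | calibrate | oracle`); every
output file records the config hash and seeds that regenerate it.

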
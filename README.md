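# parbsbm

Quantitative modelling of the bacterial **ParB·parS partition complex**:
a Monte-Carlo simulator of supercoiled circular DNA and the **stochastic
binding model** (SBM) that turns simulated chain conformations plus a
ParB-cluster concentration profile into a non-specific DNA-binding profile
comparable with ChIP-seq coverage data.

## Who this is for

Researchers studying bacterial DNA segregation (ParABS systems), protein
condensates on DNA, or plasmid supercoiling who want to (i) sample
equilibrium conformations of a torsionally constrained circular DNA
molecule, (ii) predict the ParB binding profile B(s) around a centromeric
*parS* site under different hypotheses for the cluster shape, and (iii) fit
those predictions to processed ChIP-seq coverage profiles.

## The model

**DNA.** A plasmid of `n_bp` base pairs is a closed self-avoiding rod-like
chain of `N = n_bp/30` rigid cylinders (length `l = 10.2 nm`, hard-core
radius `r_e = 2 nm`), with per-joint bending energy `κ(1 − cos θ)`
calibrated to a 50 nm persistence length and a uniform-twist torsional
energy `E_tw = (2π²C/L)·ΔTw²` with `C = 86 nm`.  The linking number `Lk` is
conserved by chain closure and non-crossing; its deficit splits as
`Lk − Lk0 = Wr + ΔTw`, with the writhe `Wr` computed from the exact
segment-pair Gauss-integral closed form.  Supercoiling density
`σ = (Lk − Lk0)/Lk0` is imposed by a stepwise annealing protocol (remove
helices, relax by Metropolis crankshaft moves, repeat down to σ = −0.08).

**Binding.** The SBM predicts the non-specific binding profile

    B(s) = ∫ 4π r² P_s(r) C(r) dr,

where `P_s(r)` is the distribution of 3-D distances between a locus at
genomic offset `s` from *parS* and *parS* itself (measured on the simulated
ensemble), and `C(r)` is the probability of finding a ParB protein at
distance `r` from *parS*.  Four cluster shapes with a common FWHM ω are
available: a *quenched* droplet (sharp boundary at ω/2), Gaussian,
exponential, and the *leaky* cluster — a saturated core of radius ω/4 plus
a 1/r halo, the long-screening-length limit (`ξ = √(D/Γ)` ≫ cell size) of
the stationary source–diffusion–dilution balance.  The leaky profile
integrates to an average protein number

    N_P = (ω/4a)³ · [1 + (3/2)((4R/ω)² − 1)]

over a nucleoid of radius `R`, with `a` the effective protein radius.

**Fitting.** Coverage profiles (TSV/bedGraph) are background-subtracted,
clipped, max-normalized, and compared with B(s) by RMSD over a fit window
(default 1.5–9 kb, which excludes promoter distortions) on a (σ, ω) grid.

## Worked example

```python
import numpy as np
import parbsbm as pb
from parbsbm import mc, observables, sbm

# anneal a 6 kb circle from sigma = 0 to -0.08 (5 runs, desk scale)
sched = mc.AnnealingSchedule.for_chain(lk0=570.0, sweeps_per_level=1200)
plan = mc.SamplingPlan(n_runs=5, frames_per_run=40)
ens = mc.run_annealing_protocol(sched, plan, pb.EnergyModel(),
                                mc.MoveParams(max_span=20),
                                n_bp=6000, seed=1)

for row in observables.gyration_curve(ens)[[0, -1]]:
    print(f"sigma {row['sigma']:+.3f}  Rg = {row['mean']:.1f} nm")

# binding profile at sigma = -0.04 for a leaky cluster of FWHM 44 nm
sig = min(ens.sigmas(), key=lambda s: abs(s + 0.04))
_h, ds = observables.estimate_Ps(ens, sig, np.arange(0, 3001, 30))
prof = sbm.binding_profile(ds, sbm.ClusterModel(kind="leaky", omega=44.0))
print(f"B(1500 bp) = {prof.values[prof.s == 1500][0]:.2f}")

# protein count of the leaky cluster in a 400 nm nucleoid
cm = sbm.ClusterModel(kind="leaky", omega=36.0)
print(round(sbm.protein_count(cm, sbm.ProteinCountParams(400.0, 20.0))))
```

prints

```
sigma +0.000  Rg = 240.6 nm
sigma -0.080  Rg = 86.5 nm
B(1500 bp) = 0.12
270
```

i.e. supercoiling compacts the molecule almost 3-fold, a locus 1.5 kb from
*parS* overlaps the cluster halo ~12% of the time, and a 20 nm effective
protein radius corresponds to ~270 ParB per cell — the order of magnitude
measured experimentally.

A `parbsbm` command-line tool wraps the same layers
(`simulate`, `analyze`, `binding-profile`, `protein-count`, `fit`,
`synth`); see `parbsbm --help`.

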
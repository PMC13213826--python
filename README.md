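# protorelay

Analysis and enhanced-sampling toolkit for **water-mediated
tautomerization** of a catalytic asparagine: after some glycosyltransfer
reactions the catalytic Asn is left in its imidic-acid form, R–C(=NH)OH,
and must be reset to the amide form R–CONH₂ through a Grotthuss-type
proton relay across one to three active-site water molecules.  This
package provides, for computational chemists and structural
bioinformaticians studying such proton-relay chemistry:

- **Water-wire detection** — hydrogen-bond graph construction (donor–
  acceptor distance ≤ 3.5 Å, donor–H–acceptor angle ≥ 150°) and search for
  directionally consistent paths OD → w₁ → … → w_k → ND (k ≤ 3), with
  competent-configuration statistics across replica trajectories.
- **Trajectory analytics** — Kabsch RMSD, per-atom RMSF, Shrake–Rupley
  SASA (1.4 Å probe), and radial hydration-shell profiles.
- **Collective variables** — rational switching-function coordination
  numbers, s(r) = 1/(1 + (r/r₀)⁶) with r₀ = 1.1 Å; the proton-transfer CV
  CV = CN_N − CN_O over the transferable protons; the FES axes
  CV1 = d(C,N) − d(C,O) and CV2.
- **Enhanced sampling** — overdamped Langevin dynamics, an OPES bias with
  an exact ΔE = 20 kcal/mol cap, free-energy-surface reweighting with
  basin/barrier extraction, and k-medoids transition-state ensembles.
- **A machine-learned committor** — a [N, 32, 32, 1] network trained with
  a variational Kolmogorov loss, yielding the reaction coordinate
  z(x) = logit q(x) and a TS-focusing bias V_K = −λΔE[4q(1−q)]²
  (λ = 0.3).
- **Synthetic generators** — active-site fixtures with certified wire
  ground truth, trajectories with a controlled competent fraction, and
  analytic two-basin surrogate landscapes with exactly calibrated barrier
  and basin offset, so the whole pipeline is testable without external
  data.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from protorelay import (
    FixtureSpec, make_trajectory, competent_stats,
    make_surrogate, estimate_landscape,
)

# trajectory of 500 frames, 30% of which hold a two-water wire
spec = FixtureSpec(n_waters=6, wire_order=2, sigma=0.05, seed=1)
traj, labels = make_trajectory(0.3, 500, spec, seed=11)
stats = competent_stats([traj])
print(f"competent: {stats.percent_mean:.1f}%  (generator used {100*labels.mean():.1f}%)")
print("order breakdown:", {k: round(v, 1) for k, v in stats.order_breakdown.items()})

# recover a calibrated two-basin landscape with OPES
pot = make_surrogate(dG=-10.0, dG_barrier=4.3)   # kcal/mol
est = estimate_landscape(pot, n_replicas=3, seed=0)
print(f"dG = {est['dG']:+.2f}  dG_barrier = {est['dG_barrier']:.2f}  "
      f"max bias range = {est['max_bias_range']:.1f}")
```

prints

```
competent: 31.4%  (generator used 31.4%)
order breakdown: {1: 0.0, 2: 100.0, 3: 0.0}
dG = -9.87  dG_barrier = 4.15  max bias range = 20.0
```

The detector reproduces the generator's competent fraction exactly frame
by frame (31.4% here is the binomial draw at p = 0.3, n = 500), every
competent frame carries the minimal wire order 2, and the sampling engine
recovers the configured basin offset (−10 kcal/mol) and forward barrier
(4.3 kcal/mol) to within a few tenths of a kcal/mol while the deposited
OPES bias range never exceeds its 20 kcal/mol cap (it saturates at
exactly 20 in the rarely visited confinement-wall region).

## Command line

A thin `protorelay` console script wraps the library:

```bash
protorelay wires --traj traj.pdb --frag CG=0,OD=1,ND=2,HO=3,HN=4
protorelay hydration --traj traj.pdb --frag CG=0,OD=1,ND=2,HO=3,HN=4
protorelay cv --traj traj.pdb --frag CG=0,OD=1,ND=2,HO=3,HN=4
protorelay sample --dg -10 --barrier 4.3 --steps 600000 --out run/
protorelay run --config run.yml --out out/     # full pipeline
```

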
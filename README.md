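# switchscape

Stochastic switching analysis of a self-activating gene circuit: who is it
for and what does it compute?

Many genes drive their own expression through a positive feedback loop —
protein promotes the opening of its own chromatin and its own transcription
— and such circuits switch stochastically between a low-expression ("off")
and a high-expression ("on") state. Whether the *gene-state* dynamics
(chromatin opening/closing) are slow, comparable, or fast relative to
protein turnover changes the character of this switching completely, yet
switching rates are hard to measure directly. `switchscape` implements the
full analysis battery for a two-state positive-feedback expression model —
and an in-silico flow-cytometry protocol that infers the switching regime
from protein-level snapshots alone.

## Model

Gene (closed/open) + mRNA (`m`) + protein (`n`), six reactions: gene
inactivation `d_g`; activation `k_g·O(n) + k_g0`; transcription
`k_r·O(n) + k_r0` (open gene); translation `k_p·m`; decays `d_r·m`,
`d_p·n`; feedback through the binding-site occupancy
`O(n) = nᵸ/(nᵸ + Kᵸ)`. The adiabaticity ratio `κ = d_g/d_p` separates the
slow (`κ ≪ 0.01`), intermediate, and fast (`κ ≫ 1`) switching regimes.

The toolkit provides:

* **`cme`** — stationary solutions of the truncated chemical master
  equation (a censoring/level-reduction solver handles ~10⁶-state
  lattices), energy landscapes `U = −ln P`, KL divergences, and mean
  first-passage times by linear solves;
* **`ssa`** — exact Gillespie simulation (numba), gene-aware tau-leaping,
  switching-time estimation, and averaged reactive switching trajectories;
* **`slow`** — the two-layer reduction: per-layer rate equations and
  linear-noise moments, and the simple / time-averaged ("modified")
  Gaussian-mixture approximations of the stationary landscape;
* **`fast`** — the adiabatic reduction, its Freidlin–Wentzell Hamiltonian
  `H(x,p) = Σⱼ aⱼ(x)(e^{νⱼ·p} − 1)`, minimum-action switching paths by a
  geometric minimum-action method, and the glued global quasi-potential;
* **`experiments`** — bistability windows in the feedback strength `K`,
  switching-time sweeps over `κ`, the cell-sorting experiment, and the
  three-way regime classifier.

## Worked example

```python
import switchscape as sw

params = sw.preset("slow")          # kappa = 0.001: slow gene switching
print(f"kappa = {params.kappa}")

m_on, n_on = sw.layer_fixed_point(1, params)
print(f"open-layer fixed point: m* = {m_on:.1f}, n* = {n_on:.1f}")

dist = sw.steady_state(params)      # truncated CME, ~1.6M states
closed, open_ = dist.gene_marginal()
print(f"stationary gene occupancy: closed = {closed:.3f}, open = {open_:.3f}")

split = sw.experiments.default_split(sw.kappa_family(100.0, params))
mst = sw.estimate_mst(params, "on_to_off", split, replicates=20, seed=1,
                      method="tau")
print(f"on-to-off mean switching time: {mst.mean:.0f} +- {mst.se:.0f} "
      f"(1/d_g = {1/params.d_g:.0f})")
```

prints

```
kappa = 0.001
open-layer fixed point: m* = 61.6, n* = 2267.3
stationary gene occupancy: closed = 0.829, open = 0.171
on-to-off mean switching time: 580 +- 135 (1/d_g = 714)
```

Reading this: the on state sits near 2267 protein copies; the gene is
closed 5/6 of the time (dwell-time balance `d_g/(d_g+k_g0)`, reproduced by
the CME to half a percent); and in the slow regime the on→off switching
time is set by the gene-inactivation lifetime `1/d_g = 714` — the Monte
Carlo estimate agrees within its standard error.

A command-line layer wraps the same functions
(`switchscape solve-cme | simulate | mst-sweep | k-boundary | landscape |
gmam | sort-experiment | classify`), each taking a YAML config, a seed, and
an output directory; results are written as CSV/JSON/HDF5 with metadata
headers.

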
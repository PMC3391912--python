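# termitory

A stochastic lattice simulator of subterranean termite foraging
territories under seasonal climate forcing, with the analysis chain used
to study how climate change reshapes territory size distributions:
rank-size distributions, a two-regime semi-log slope *m*, and
SOM + Ward clustering of the (*T*, *σ*, *m*) parameter surface.

## The model

Foraging territories of *Coptotermes formosanus* (Formosan subterranean
termite) colonies compete on an *L* × *L* lattice (default *L* = 200).
Every cell is **empty**, **active** (a live tunneling tip that can extend
the territory) or **inactive** (occupied, no longer growing).  A static
random landscape assigns each cell a tunneling-ease probability
*P*<sub>trans</sub> ∈ [0, 1].  *N* founding pairs are seeded at random
positions, one territory label each.

Seasons alternate as a step function:

- **Summer** (*T* synchronous steps; *T* = 36 matches the summer of
  New Orleans, Louisiana).  Each active cell picks one empty Moore
  neighbor with probability ∝ *P*<sub>trans</sub> and colonizes it with
  probability *P*<sub>trans</sub>(target).  Territories never overlap; a
  cell contested by *k* territories is awarded uniformly (probability
  1/*k*).  An active cell whose attempt fails, loses a contest, or is
  enclosed by ≥ 7 inactive Moore neighbors turns inactive.
- **Winter** (one step).  Each territory is pruned back to *σ* percent of
  its cells, removing the cells farthest from the founding seed first
  (the seed always survives); survivors all turn inactive, then a few
  distal cells (default 5) are reactivated, sampled ∝ distance from the
  seed, to restart growth at the colony periphery.

Climate forcing is encoded by the summer duration *T* and the winter
retention *σ*.  Runs cycle until the post-summer total cell count is
steady (< 1% relative change) or a cycle cap is hit.

The analysis measures, per (*T*, *σ*, *N*): the replicate-averaged
territory sizes ⟨*A*⟩ in descending rank order, and the absolute slope
*m* of ln ⟨*A*⟩ vs rank over the front (large-territory) segment of a
two-segment least-squares fit — larger *m* means greater size inequality
among the dominant colonies.  The (*T*, *σ*, *m*) records are min-max
scaled, mapped onto a 6 × 7 Kohonen self-organizing map, and the trained
prototypes partitioned with Ward's linkage (default 8 clusters).

## Worked example

```python
import termitory as tm

cfg = tm.SimConfig(L=100, N=30, T_summer=10, sigma=30.0, rng_seed=42)
res = tm.run_simulation(cfg)
print(res.cycles_run, res.steady, res.final_grid.total_termite_cells())
# 22 True 843

spec = tm.SweepSpec(T_values=(10,), sigma_values=(10, 30, 50), N_values=(30,),
                    n_replicates=10, base=tm.SimConfig(L=100, N=30),
                    master_seed=42)
print(tm.run_sweep(spec)[["T", "sigma", "m_front", "mean_total_size"]])
```

```
 T  sigma   m_front  mean_total_size
10     10  0.117991            424.3
10     30  0.065344            831.5
10     50  0.052359           1019.2
```

The run above reaches a steady seasonal regime after 22 cycles with 843
occupied cells across the 30 territories.  In the sweep, higher winter
retention *σ* leaves more and larger territories (mean total size grows
from 424 to 1019 cells) while the front slope *m* falls — under these
exact local rules, generous winters even out the large colonies.
Longer summers steepen the slope: at *σ* = 30, *m* rises from ≈ 0.065
(*T* = 10) to ≈ 0.086 (*T* = 50), the competition signature of a longer
growing season.

The same pipeline is scriptable from a shell:

```sh
termitory simulate --config run.json --seed 7 --out out/   # grid snapshots
termitory sweep    --preset desk --seed 7 --out out/       # m_front table
termitory analyze  --sizes sizes.csv --out out/            # rank-size + fit
termitory som      --sweep out/sweep.csv --k 8 --out out/  # SOM + Ward
```

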
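# ionbind

Replica-ensemble ion-binding analysis for membrane transporters.

Secondary active transporters of the SLC6 family (the serotonin transporter
SERT being the archetype) recruit Na⁺ from the extracellular medium through
an outer vestibule into two buried sites, NA1 and NA2. Because association
is fast (ns–µs), it can be studied by running many short independent MD
trajectories from different starting conformations and treating the
ensemble statistically: each replica either shows a first binding event at
some time *t* or is right-censored at the end of its window. `ionbind`
turns such replica sets — real trajectories or synthetic ones with known
ground truth — into binding statistics:

- **Event detection** — vestibule entry through a salt-bridge gate
  (plane + lateral-radius predicate), site occupancy with hysteresis
  thresholds on the distance to the coordinating-atom centroid, explicit
  censoring, binding-order statistics, and ion-release routing.
- **Association kinetics** — the cumulative count of replicas with a first
  event, *y(t)*, is fitted by the constrained mono-exponential

  *y(t) = N·(1 − e^(−bt))*,  with the plateau *N* fixed to the number of
  replicas; *t*₁/₂ = ln 2 / *b*, and the bimolecular association constant
  *k*_on = *b* / [Na⁺]. A closed-form censored-exponential MLE,
  *b* = *n*_events / (Σ *t*ᵢ + *n*_cens·*T*), is always computed alongside
  as an independent estimator, and a replica-level bootstrap gives a 95% CI.
- **Spatial fields** — ion density and mean displacement-rate maps on
  0.1 nm grids in a common Cα-superposed frame (Kabsch), written as OpenDX.
- **Site geometry** — binding-site *compactness* (mean coordinating-atom
  distance to their centroid), pre/post-binding splits with the value at
  the moment of binding, 1 ns running averages, and all-vs-all RMSD
  matrices of the coordinating atoms ordered by binding time — the
  induced-fit signature.
- **Synthetic replica generator** — a hybrid event-driven mode with exact
  exponential binding times (kinetics ground truth) and an
  overdamped-Langevin spatial mode in a vestibule-shaped potential
  (geometric ground truth), plus an Ornstein–Uhlenbeck coordinating-atom
  process that compacts upon binding.

## Worked example

```bash
ionbind run --config examples/synthetic.yaml --out out --seed 2
```

generates the default 51-replica × 150 ns synthetic study at 150 mM NaCl,
detects events, and writes the full report bundle. `out/kinetics.json`
from that run contains (values are per site; `b` in ns⁻¹):

| site      | b (ns⁻¹) | t½ (ns) | k_on (M⁻¹s⁻¹) | events | censored |
|-----------|----------|---------|----------------|--------|----------|
| VESTIBULE | 0.1227   | 5.65    | 8.18·10⁸       | 51     | 0        |
| NA1       | 0.00731  | 94.8    | 4.87·10⁷       | 32     | 19       |
| NA2       | 0.00244  | 284     | 1.62·10⁷       | 16     | 35       |

Read: every replica's vestibule gained an ion (half-time ≈ 5.7 ns); NA1
fills faster than NA2; roughly 2/3 (NA1) and 1/3 (NA2) of replicas bind
within 150 ns, the rest are censored. These are one seed's stochastic
realisations of the generator's configured rates (4.2·10⁷ and 1.9·10⁷
M⁻¹s⁻¹). `out/binding_order.json` partitions the replicas by which site
filled first, `out/compactness_summary.csv` holds the per-replica
pre/post-binding compactness means (the NA1 site closes by ≈ 0.1 nm on
binding under the default geometry process), and `out/density.dx` /
`out/displacement.dx` are ready for any OpenDX-capable viewer.

For real data, replace the `synthetic:` block with

```yaml
real:
  topology: system.gro
  trajectories: [rep0.xtc, rep1.xtc, ...]
  concentration_molar: 0.15
```

and adapt the gate anchors and coordinating-atom selections
(`resnum:atom_name` pairs) to your topology's naming.

## Library use

```python
import ionbind as ib
from ionbind.synthetic import SyntheticConfig, generate_replica_set

cfg = SyntheticConfig(n_replicas=51, duration=150.0, dt_frame=0.05)
replica_set, truth = generate_replica_set(cfg)

top = replica_set.topology
sites = [ib.SiteDefinition("NA1", ib.select_atoms(top, "96:O, 98:CG, 101:OD1, 336:O, 336:OG, 368:OD1"))]
table = ib.build_event_table(replica_set.trajectories, None, sites,
                             ib.select_ions(top))
fit = ib.fit_constrained_monoexponential(
    ib.cumulative_curve(ib.first_binding_times(table, "NA1"), 150.0, 0.1),
    concentration=replica_set.ion_concentration)
print(fit.t_half, fit.k_on)
```

See `docs/methods.md` for the models, defaults and their rationale.
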
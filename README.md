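# rhizoconduct

Simulation of how declining soil phosphorus reorganizes the root system of
young maize (*Zea mays* cv. B73) and lowers its water-uptake capacity.

Soil P availability changes a plant's architecture — thinner axial roots,
slower crown-root and leaf elongation under deficiency — and those
architectural shifts change the root system's intrinsic capacity to take up
water.  `rhizoconduct` is aimed at root-phenotyping and functional–structural
plant modelling groups who want to go from measured architecture parameters
(or traced RSML root systems) to the root-system conductance *K*<sub>rs</sub>
of growing plants, per soil-P treatment, without any external tooling.

The package couples three pieces:

1. **Stochastic architecture simulation.**  Plants are assembled from
   cylindrical segments.  Every organ elongates along the negative
   exponential law *l*(*t*) = *l*<sub>max</sub>(1 − e^(−*r t*/*l*<sub>max</sub>)),
   with the initial elongation rate *r* and all other organ parameters drawn
   per organ from measured (mean, s.d.) tables for four soil-P treatments
   (P0 = severe deficiency, 1.8 mg P/100 g soil … P3 = sufficient,
   7.7 mg P/100 g soil).  Seminal roots, crown-root whorls and laterals
   follow the measured emergence schedule and branching geometry.
2. **Hydraulic network solver.**  Each root segment exchanges water with the
   soil through a radial conductance *K*<sub>r</sub> = 2π *a* d*l*
   *k*<sub>r</sub>(age) and conducts axially with *K*<sub>x</sub>(age);
   the stem takes no radial water and conducts by Hagen–Poiseuille,
   *K*<sub>x</sub> = π *a*<sub>xyl</sub>⁴/(8 μ).  Steady-state mass balance
   over the segment tree is a sparse SPD linear system whose solution gives
   nodal xylem potentials, per-segment flows, the standard uptake fraction
   (SUF, summing to 1) and

   *K*<sub>rs</sub> = *T*<sub>act</sub> / (ψ<sub>sr,eff</sub> − ψ<sub>collar</sub>),  ψ<sub>sr,eff</sub> = SUFᵀ ψ<sub>sr</sub>,

   which is independent of the chosen boundary potentials (linearity).
3. **P-response functions.**  Axial root radius is linear in soil P, crown
   elongation is capped-linear in the P-to-biomass ratio *PB*, leaf
   elongation is linear in P.  Fitted once, they turn a single "general"
   parameter set plus a soil-P level into a full treatment parameterization.

A synthetic-data module generates every input with known ground truth
(growth series, RSML rhizotron traces, hydraulic profiles, response data),
so the whole pipeline is testable offline.  The packaged age-dependent
conductivity profile is a synthetic stand-in with literature-shaped curves
(see `docs/methods.md`).

## Worked example

```python
import rhizoconduct as rc

params = rc.build_treatment("P3")              # measured high-P tables
net = rc.simulate_plant(params, 28.0, rng_seed=1)
print(len(net.segments), net.count_organs("crown"))
print(rc.summarize(net)["roots-total"])
for t, k in rc.krs_time_series(net, rc.HydraulicProfile.default(),
                               [7, 14, 21, 28]):
    print(f"day {t:4.0f}: K_rs = {k:.4f} cm2/d")
```

prints

```
7099 11
{'length': 1636.4, 'surface': 525.0, 'volume': 15.5}
day    7: K_rs = 0.0018 cm2/d
day   14: K_rs = 0.0063 cm2/d
day   21: K_rs = 0.0128 cm2/d
day   28: K_rs = 0.0198 cm2/d
```

One stochastic 28-day P3 plant here has 7099 segments (11 crown roots in
three whorls plus primary, seminals and their laterals), 1636 cm of root and
15.5 cm³ of root volume; its conductance grows from 0.0018 to about
0.02 cm² d⁻¹ as the root system extends and its xylem matures.  Ensembles
over seeds (`rc.run_ensemble`) give the treatment-level picture: high-P
plants end up with a distinctly higher *K*<sub>rs</sub> than all three
deficient treatments, whose conductances stay close to each other — the
degree of deficiency matters less than deficiency itself.

The same experiment from the shell:

```bash
rhizoconduct ensemble --treatment all --n 100 --times 7,14,21,28 --out results
rhizoconduct simulate --treatment P0 --days 28 --seed 3 --out p0_plant
rhizoconduct krs --network p0_plant/segments.csv --out krs.json
```

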
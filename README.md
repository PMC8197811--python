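# catdesc

Reactive descriptors and linear barrier scaling for enzyme SN2 catalysis,
with a nudged-elastic-band (NEB) reaction-path stage on analytic model
surfaces.

## The problem

The first chemical step of haloalkane dehalogenase (DhlA) acting on
1,2-dichloroethane is a bimolecular nucleophilic substitution: the
carboxylate of Asp124 (modelled as acetate, AcO⁻) attacks the substrate
carbon C1 while chloride Cl1 departs. How much of the rate acceleration
comes from the aromatic residues lining the active site (Trp125, Trp175,
Phe172), and can a simple transition-state property *predict* the barrier
in a different environment, such as bulk water?

`catdesc` answers this with two scalar descriptors evaluated at the
stationary points of the reaction path:

- **D<sub>cat</sub> = d<sub>l</sub> − d<sub>f</sub>** — the length of the
  breaking C1–Cl1 bond minus the length of the forming O1–C1 bond, both at
  the transition state (Å). A larger D<sub>cat</sub> means a "later",
  more reactive TS.
- **Q<sub>cat</sub> = q<sub>TS</sub> − q<sub>RC</sub>** — the summed
  signed partial charge of the nucleophile group at the transition state
  minus at the reactant complex (e). A larger Q<sub>cat</sub> means
  faster charge transfer toward the leaving group.

Across a series of truncated active-site environments (three, two, one,
zero residues) each descriptor scales linearly with the activation
barrier ΔE‡, a Brønsted–Evans–Polanyi-type relation

&nbsp;&nbsp;&nbsp;&nbsp;ΔE‡ = α·x + β,&nbsp;&nbsp;x ∈ {D<sub>cat</sub>, Q<sub>cat</sub>},

fitted here by ordinary least squares. Evaluating the fitted line at a
held-out environment's descriptor value predicts its barrier — the
package's worked case is the aqueous reaction, whose predicted barrier
comes out *above* every residue-containing environment: water hinders
this SN2 step, the enzyme accelerates it.

The NEB stage reproduces the path-level machinery on 2-D analytic
surfaces (a tunable double-well SN2 surrogate and the Müller–Brown
benchmark): chain-of-states optimization with improved tangents, a
climbing image that converges onto the saddle, saddle verification by
gradient norm plus exactly one negative Hessian eigenvalue (the 2-D
analogue of one imaginary frequency), and endpoint relocation along the
unstable mode.

## Worked example

Generate the built-in demonstration series (five environments with the
descriptor values and free-energy barriers of the acetate +
dichloroethane system; water is flagged `role: predict` and held out of
all fits) and run the full pipeline:

```sh
catdesc simulate --outdir demo --seed 1
catdesc report --config demo/series.yaml --outdir demo/report
cat demo/report/descriptors.tsv
```

```
label   dcat_angstrom   qcat_e  barrier_kcal_mol        role
3       0.43    0.21    15.4    fit
2       0.30    0.17    17.1    fit
1       0.04    0.09    19.3    fit
0               0.05    24.3    fit
water   -0.10   0.04            predict
```

Each row is one environment (labelled by its residue count): descriptors
at full precision rounded to two decimals for display, barriers in
kcal/mol. The zero-residue environment carries no D<sub>cat</sub> (its
TS bond lengths are not part of the series inputs), so the
D<sub>cat</sub> line is fitted on three points and the Q<sub>cat</sub>
line on four. Fitting and predicting the held-out water environment:

```sh
catdesc fit --config demo/series.yaml --descriptor qcat --out qcat.json
catdesc predict --model qcat.json --x 0.04
```

```
qcat: slope -50.00, intercept 25.53, r² 0.894 (n=4) -> qcat.json
qcat=0.04: barrier 23.5 ± 2.0 kcal/mol  [extrapolated]
```

The negative slope is the catalysis story in one number: every 0.01 e of
extra charge transfer at the TS is worth about half a kcal/mol of
barrier. The water prediction (23.5 kcal/mol from Q<sub>cat</sub>, 20.8
from the three-point D<sub>cat</sub> line, both flagged as
extrapolations) sits well above the residue-containing barriers
(15.4–19.3 kcal/mol): the aqueous environment impedes the reaction.

The NEB stage runs from the same entry point:

```sh
catdesc neb --pes sn2 --start=-1,0 --end 1,0 --images 12 --out path.tsv
```

converges the climbing image onto the saddle of the symmetric double
well at the origin, recovering the closed-form barrier V0.

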
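# Methods

## Descriptors

Both descriptors are functions of stationary-point data only; no
electronic-structure calculation happens in this package — geometries,
charges, and barriers are ingested as data.

**D<sub>cat</sub>** is computed from the transition-state geometry alone:
the Euclidean C1–Cl1 distance minus the O1–C1 distance, both in Å. The
reactant- and product-complex geometries are carried for completeness but
play no role in the descriptor; a variant referencing RC distances was
deliberately not implemented, because the descriptor's defining property
— TS "lateness" — is a TS-internal quantity.

**Q<sub>cat</sub>** is the arithmetic sum of signed atomic charges over
the nucleophile selection at the TS minus the same sum at the RC, in
units of e. The package is agnostic about the population-analysis scheme
that produced the charges (Mulliken, ESP, NPA, ...); the scheme name is
carried as metadata only, and charges from different schemes should never
be mixed within one series. A fragment reported as a single grouped
value (e.g. the whole CH₃CO₂ group) is representable as one pseudo-atom
entry, making the singleton group sum the degenerate case of the general
one.

Descriptors are computed and stored at full double precision; only the
TSV report layer rounds (two decimals for descriptors, one for
barriers).

## Scaling fits and prediction

The barrier–descriptor relation is fitted by **unweighted ordinary least
squares** of barrier on descriptor (statsmodels OLS under the module
surface). No robust, weighted, or multivariate (joint
D<sub>cat</sub>+Q<sub>cat</sub>) variants: with three to five points per
series they would be noise-fitting. Reported per fit: slope, intercept,
R², residual standard error, n, and the descriptor range. With exactly
two points the line interpolates; R² is then reported as 1 with an
explicit warning since the variance decomposition has zero residual
degrees of freedom.

Prediction at a new descriptor value x returns α·x + β with the
standard prediction-interval SE, s·√(1 + 1/n + (x−x̄)²/S<sub>xx</sub>).
Predictions outside the fitted descriptor range are permitted — the
aqueous environment is exactly such a case — but always flagged as
extrapolations.

On the four-point Q<sub>cat</sub> series (0.21, 0.17, 0.09, 0.05 e
against 15.4, 17.1, 19.3, 24.3 kcal/mol) plain OLS gives slope −50.0
kcal/mol·e⁻¹, intercept 25.5 kcal/mol, and a water (Q<sub>cat</sub> =
0.04) prediction of 23.5 kcal/mol. Published analyses of this system
quote about 24.2 kcal/mol for the same extrapolation without stating the
fitting procedure; the ~0.7 kcal/mol gap is within the prediction SE
(±2.0) and is documented here rather than tuned away. The
D<sub>cat</sub> line in the demo series uses only three points (see
*Synthetic data* below) and predicts 20.8 kcal/mol for water — lower
than a four-point fit would give, again reported as-is. Both
predictions land above every residue-containing barrier, which is the
scientifically meaningful statement.

Environment comparisons are plain barrier differences against a chosen
reference, sign convention: negative = catalysis relative to the
reference.

## Model surfaces and NEB

Two analytic 2-D surfaces stand in for a quantum-chemistry engine. Two
dimensions is the minimum for a first-order saddle — a stationary point
with exactly one negative Hessian eigenvalue, the configuration-space
analogue of a TS with one imaginary vibrational frequency. Energies are
dimensionless model units; the mapping onto kcal/mol labels happens only
when the synthetic module fabricates series data.

- `sn2`: V = V0·(x²−1)² + asym·x + ½k(y−cx)². Symmetric case (asym = 0,
  c = 0): minima exactly at (±1, 0) with V = 0, saddle exactly at the
  origin with V = V0 — every NEB result on it has a closed form.
- `muller_brown`: the standard four-term Müller–Brown benchmark with the
  literature constant set fixed as module constants. Its three minima
  and two saddles are *never* hard-coded: an in-repo oracle
  (`find_stationary_points`) locates them by a dense-grid scan (400²
  default) of the gradient norm followed by Newton polishing, and every
  NEB assertion tests against that oracle. Oracle locations are stable
  to grid refinement (400 → 600 per axis moves nothing by more than
  1e-3).

The NEB implementation uses the improved (energy-weighted) tangent — the
standard remedy for kinked bands — with the usual nudging: true force
perpendicular to the tangent, spring force along it, endpoints
immutable. The optimizer is a FIRE-type quenched-velocity integrator
with a per-image step cap (plain steepest descent is available for
debugging); it is fully deterministic, so identical configurations give
identical iteration histories. The climbing image (spring-free, parallel
force inverted) activates only after the plain band converges to 10× the
force tolerance, so it never climbs on an unequilibrated band.
Convergence requires the maximum per-image NEB force norm below the
tolerance (default 1e-3 model units); non-convergence within the
iteration budget is reported through a flag, not an exception. Defaults
(12 images, spring k = 1, 5000 iterations) are deliberate package
choices surfaced in `NEBConfig` — chain-of-states parameters are always
system-dependent, and the Müller–Brown tests use stiffer springs and
smaller steps to match its much larger force scale.

Saddle verification computes the gradient analytically and the Hessian
by symmetric central differences (default steps: gradient 1e-5, Hessian
1e-4, balancing truncation against round-off in double precision); the
verdict requires gradient norm below tolerance *and* exactly one
negative eigenvalue. Endpoint relocation displaces ±δ along the
negative-eigenvalue eigenvector and quenches by capped-step steepest
descent with a Newton polish. Steepest descent, not a quasi-Newton
minimizer, is essential here: the quench must follow the gradient-flow
line into the *adjacent* basin, and L-BFGS-sized steps can hop across
the shallow middle minimum of Müller–Brown into the wrong well.

## Synthetic data

The generator fabricates complete, loadable series: XYZ geometries,
charge CSVs, a YAML config. Geometries are minimal collinear
O1–C1–Cl1 triples (optionally padded with inert spectator atoms): the TS
places O1–C1 at 2.0 Å and C1–Cl1 at 2.0 + D<sub>cat</sub> Å, so the
prescribed descriptor is encoded exactly; RC/TS charge tables encode the
prescribed Q<sub>cat</sub> the same way. Noise applies to barriers only
— Gaussian with an explicit, mandatory seed — because in real series the
barrier is the uncertain quantity while descriptors are read off
optimized structures. σ = 0 reproduces every prescribed number exactly
(the basis of the round-trip tests), and identical specs produce
byte-identical trees.

The built-in demo series carries the published values for the acetate +
dichloroethane system: D<sub>cat</sub> 0.43/0.30/0.04 Å and
Q<sub>cat</sub> 0.21/0.17/0.09/0.05 e for three/two/one/zero residues,
free-energy barriers 15.4/17.1/19.3/24.3 kcal/mol, and water
(D<sub>cat</sub> −0.10 Å, Q<sub>cat</sub> 0.04 e) as a held-out
prediction environment. The zero-residue D<sub>cat</sub> is not among
the available inputs, so that environment contributes charge-transfer
data only and the D<sub>cat</sub> fit uses three points. A logistic
charge-evolution profile (start/end charge, midpoint, width; rescaled so
the endpoints are met exactly) models how the nucleophile's negative
charge flows to the leaving group along the normalized reaction
coordinate.

What the synthetic data does *not* emulate: real active-site geometry
(no residues, no conformational ensemble), charge-scheme physics
(charges are prescribed, not derived from wavefunctions), or correlated
errors between descriptors and barriers. Passing tests therefore
demonstrate that the *pipeline* — parsing, selection resolution,
descriptor arithmetic, fitting, prediction, ordering — is correct, not
that the descriptors themselves are transferable to new chemistry.

## Numerical and design choices

- Units fixed globally (Å, e, kcal/mol); no conversion layer.
- 1-based atom indices in all user-facing files (chemistry convention);
  the Python API otherwise follows 0-based numpy conventions, e.g. the
  image index returned by `locate_ts` (the CLI path TSV prints 1-based
  image indices).
- Free-energy barriers are the default series quantity; a
  `barrier_kind: potential_energy` config flag selects the
  potential-energy variant used for stepwise residue comparisons.
- Missing charge tables are tolerated at load time and rejected at
  Q<sub>cat</sub> computation with the environment label in the message
  (fail late, fail precisely).
- Equal-energy path maxima tie-break to the lowest index with a warning;
  ties in descriptor ordering are reported, never silently broken, and
  void the monotonicity verdict.
- Test problem sizes: 400² oracle grids, 12-image bands, 50-environment
  noisy series, 200-replicate coverage checks — all chosen to make each
  statistical assertion sharp at interactive runtimes.

## Known limitations

- No QM/MM, solvent boxes, or free-energy sampling along the band; the
  aqueous environment enters purely as one more data row.
- No uncertainty on descriptor inputs (x-errors) in the fits.
- The NEB stage is 2-D by design; it validates the algorithmics, not
  3N-dimensional molecular paths.
- With n ≤ 5 points per fit, prediction intervals are wide and R² is an
  unstable summary; the package reports both rather than hiding them.
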
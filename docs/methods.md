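# Methods

## Model overview

`brushgate` models pressure-driven flow through a cylindrical nanopore whose
inner wall is grafted with polymer chains, and the gating of that flow by a
conformational transition of the grafted layer.  The computation is a
three-stage pipeline: (i) the equilibrium monomer density profile of the
grafted layer from strong-stretching mean-field theory, (ii) the velocity
profile and flow rate from the Brinkman equation with density-dependent
permeability, and (iii) for pH-responsive polypeptide brushes, the
Zimm-Bragg helix-coil state that reshapes the layer as the stimulus varies.
Units are reduced throughout: lengths in the monomer size `a`, energies in
`kT`; viscosity and pressure gradient enter only as scale factors and
default to 1.  The flow field is assumed not to deform the brush (low
Weissenberg number), and the wall-monomer interaction is neglected, so the
density is maximal at the wall.

## Strong-stretching brush on a concave cylindrical wall

Chains of `N` monomers are grafted at density `σ_g` (chains per `a²`) to the
inside of a cylinder of radius `R`.  In the strong-stretching limit each
chain follows its classical path along the pore radius and all chains reach
the wall in the same "time" of `N` monomer steps.  This equal-time condition
has three exact consequences used here:

- the local stretching of a chain ending at `h′` is
  `E(h, h′) = (π/2N) √(h′² − h²)`, which satisfies the chain-length
  constraint `∫₀^{h′} dh/E = N` for every end position (the constraint is a
  unit test);
- the self-consistent molecular field is harmonic, so the volume fraction is
  parabolic, `ν Φ(h) = λ − B h²` with `B = 3π²/(8 p N²)` (`p` monomers per
  Kuhn segment enters the chain elasticity, not `E`);
- a monomer residing at height `h` carries elastic free energy `B h²`, so
  the per-chain elastic energy reduces to a local functional,
  `F_el = ∫ c(h) B h² dV / n_chains`.  This is an exact algebraic reduction
  of the `g/E` double quadrature (a test verifies the two routes agree), and
  it makes `ΔF(H)` available in closed form for the parabolic profile.

The multiplier `λ` is fixed by annular monomer conservation,
`∫₀^H c(h)(R − h) dh = R σ_g N` per unit pore length with `c = Φ/(πa³/6)`.
On the returned grid `λ` is solved so the *trapezoidal* balance holds
exactly (bracketed root-find with the profile clipped at zero), so the
conservation invariant is satisfied to machine precision regardless of grid
resolution.

The free-end distribution `g(h′)` solves the Abel-type equation
`Φ(h) = (πa³/6) σ_g R/(R − h) ∫_h^H g(h′)/E(h, h′) dh′`.  The annular weight
`R/(R − h)` follows from chains grafted at radius `R` spreading their
monomers over shrinking annuli; it reduces to the planar kernel as `R → ∞`
and makes `∫ g dh′ = 1` and monomer conservation hold simultaneously and
exactly.  Numerically the equation is transformed to the squared coordinate
`u = h′²`, where the kernel is the classical Abel kernel `1/√(u − t)`;
`g/2h′` is taken piecewise-constant per sub-interval, the kernel integrated
analytically, and the collocated triangular system back-substituted from the
outer edge.  Discretization noise can leave tiny negative values in `g`:
values above `−10⁻⁸` are clipped to zero and `g` renormalized; anything more
negative raises an accuracy warning.  Compressed layers (trial `H` below the
natural height) have an integrable `1/√` singularity of `g` at the edge that
this scheme resolves only coarsely (few-percent error in the second moment);
at the equilibrium height `g` vanishes smoothly and the scheme is accurate
to ~10⁻⁴.

`ΔF(H) = F_vol + F_el` decreases monotonically as a compressed layer
relaxes and is constant beyond the natural height `H_nat` where the edge
density vanishes (`λ = B H_nat²`) — trial heights beyond it are not
realizable with nonnegative `g`.  The equilibrium height is found by bounded
scalar minimization of `ΔF` on `(0, min(H_nat, R)]` to `10⁻⁴ a`; if even the
pore-spanning layer keeps positive edge density the result is pinned at
`H = R` and flagged `pore_spanning`.  The implementation is validated against
an independent oracle: direct SLSQP minimization of the discretized
free-energy functional over piecewise-constant `Φ` under the conservation
constraint, with no parabolic ansatz.

Profile grids are uniform with spacing ≤ 0.25 `a` (at least 41 nodes),
finer than the flow solver's default shell of 1 `a`, to resolve the
parabolic edge; quadrature is trapezoidal.

The solvent-quality scalar `ν ∈ (0, 1]` multiplies the excluded volume
`πa³/6` (second-virial treatment only; `ν ≤ 0` — theta/poor solvent needing
a third virial — is rejected).  Chain length `N` is physically a count but
the geometry accepts fractional values ≥ 1: the mean-field theory extends
smoothly, and composite helix/coil layers use a continuous coil length (see
below).

## Brinkman flow

The axial momentum balance
`μ (1/r) d/dr(r dv/dr) − (μ/k(r)) v = −G` is discretized on annular shells
of thickness `dr` (default 1 `a`, overridable for convergence studies).
Each shell's permeability is `k_i = a²/Φ_i²`, the literal density-permeability
law with no extra drag prefactor; `Φ_i` is the exact radial mean of the
piecewise-linear density profile over the shell, evaluated on the union of
the shell edges and the profile grid.  The volume average (rather than the
two edge nodes) matters for composite helix/coil profiles, whose step
discontinuity would otherwise alias on the flow grid and put spurious jumps
into `K(pH)`.  Polymer-free shells get `k = ∞` and the equation reduces to
Stokes flow.

The primary solver assembles the symmetric finite-difference stencil —
conservative fluxes `r_{i±1/2}`, a symmetry stencil `4(v₁ − v₀)/dr²` at the
axis, Dirichlet `v(R) = 0` at the wall — and solves the tridiagonal system
directly (unconditionally stable; the discrete momentum residual is at
rounding level).  A shooting solver marching the same stencil outward with
secant iteration on the centerline velocity is kept as a cross-validation
path; since the problem is linear the secant converges immediately and the
two agree to rounding, though marching loses digits through thick dense
layers — the direct solve is always the production path.

Flow rate `Q = ∫ 2πr v dr` uses Simpson quadrature (exact for the cubic
Poiseuille integrand, so the ungrafted pore returns `K = 1` to machine
precision); `Q₀ = πGR⁴/(8μ)` is analytic.  Oracles: the open pore against
Poiseuille, the uniformly filled pore against the modified-Bessel closed
form `v = (Gk/μ)[1 − I₀(r/√k)/I₀(R/√k)]` (evaluated with scaled Bessel
functions to avoid overflow).

## Zimm-Bragg pH gating

The helix-coil state of grafted poly(L-glutamic acid) uses the Zimm-Bragg
weights: `s` per helical residue and `σ_ZB` per helical run (first-residue
helix pays nucleation).  The finite-chain helix fraction is the exact
logarithmic derivative `θ = (s/N) ∂lnZ/∂s`, computed by propagating
`(Z, dZ/ds)` through the transfer-matrix product with per-step rescaling —
no series truncation, no finite differences.  `σ_ZB = 1` reduces to
independent residues, `θ = s/(1+s)`; the infinite-chain closed form
`θ∞ = 1/2 + (s−1)/(2√((s−1)² + 4σ_ZB s))` is approached as a pure `1/N` end
fraying (the gap halves when `N` doubles), which the tests assert as the
convergence law.

The pH dependence enters through thermodynamic linkage of the side-chain
ionization,

    s(pH) = exp(−Δg_hc) · (1 + 10^(pH − pKa_h)) / (1 + 10^(pH − pKa_c)),

strictly decreasing in pH with plateaus at both extremes.  Defaults:
`Δg_hc = −0.4 kT` (helix favored when protonated), `pKa_c = 4.4`,
`pKa_h = 6.0`, `σ_ZB = 10⁻³`, placing the computed transition midpoint at
pH\* = 4.11 with a width of ~0.3 pH units for `N = 480` — between pH 4 and
6 as observed for PLGA-grafted pores.  All are configuration-exposed.

The conformational state maps onto a density profile with a two-layer
construction: the `θN` helical residues of each chain pack into a dense
annulus at the wall (packing fraction `φ_pack = 0.9` by default), of
thickness `t_h` from exact volume balance; the remaining `N_c = (1−θ)N`
residues form a strong-stretching coil brush grafted at the annulus surface
`R_eff = R − t_h` with the areal chain number conserved
(`σ_eff = σ_g R/R_eff`).  `N_c` is kept continuous: rounding it would freeze
the coil between integer steps while the annulus still thins, breaking
monotonicity of the response; a residual coil block shorter than one residue
is dropped (sub-residue bookkeeping, within the one-residue tolerance of the
layer accounting).  If the helical content alone would overfill the pore the
layer is flagged `pore_blocked`.  This mapping is this package's concrete
realization of the helix-coil gating idea; it is conformational only — no
Poisson-Boltzmann electrostatics, no charge regulation beyond the two-state
pKa linkage.

Composing the map `pH → s → θ → profile → K` gives the valve characteristic.
A known limitation: very near the fully-helical end the response has a
genuine overshoot of ~2·10⁻⁴ in `K` (0.03% of the response range) — thinning
the nearly solid annulus opens the pore slightly faster than the still-short
coil blocks it — so "monotone decreasing" holds to a 5·10⁻⁴ tolerance, not
strictly.  The Angstrom-to-`a` conversion for laboratory pore sizes uses
`a = 3.8 Å` (one peptide backbone repeat) by default and only at the
configuration boundary.

## Valve response and design scans

Responses are fitted with the overflow-safe logistic
`K(α) = K₂ + (K₁ − K₂)·expit(−β(α − α₀))`; under this convention a response
that falls with the stimulus fits with `β > 0` (the sign of `β` encodes the
response direction).  Initialization: plateaus from the endpoints,
inflection at the steepest sampled slope, `β` from the logistic midpoint
slope identity; fitting is Levenberg-Marquardt least squares.  A flat curve
raises "no transition detected".

`design_scan` evaluates `ΔK = K(pH_open) − K(pH_closed)` (defaults pH 3/7)
over grids of `R`, `σ_g` and `N`.  `ΔK(N)` rises while lengthening chains
closes the high-pH state faster than it degrades the low-pH state, peaks
when the closed-state layer span becomes comparable to the pore radius, and
falls as the open state also degrades; the optimum `N*` is reported per
`(R, σ_g)` with an `edge` flag when it is censored by the grid, plus the
closed-span/R diagnostic (0.7–1.0 across the tested grids).  Scans are
sequentially deterministic: identical inputs give identical tables.

## Problem sizes and defaults used in tests

The test suite and the reproduction script run desk-scale problems: pores of
`R = 100–210 a` with `N ≤ 1200`, profile grids of a few hundred nodes,
pH grids of 21–41 points, and a design scan of 2×2×11 grid points — each
full pipeline evaluation takes milliseconds, the whole suite seconds.
Exhaustive Zimm-Bragg enumeration oracles use `N ≤ 12`; the planar
brute-force functional minimization uses 160 unknowns.

## Known limitations

- Second-virial mean field only: no theta/poor-solvent collapse (`ν ≤ 0`),
  and volume fractions approaching 1 abort with a validity error.
- No wall-monomer attraction (density maximal at the wall, unlike
  simulation profiles that dip at contact); no interdigitation model when
  opposite-wall layers would overlap (`H` capped at `R`).
- No shear deformation of the brush by the flow; no electro-osmosis, solute
  transport or ionic conductivity.
- The helix/coil layer mapping is a deliberately simple two-layer
  construction; it reproduces the qualitative valve behavior, not measured
  permeability values.
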
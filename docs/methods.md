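# Methods

## Model

The bundled system is a pair of chiral replicators, 1R and 2R, in D and L
enantiomeric forms, coupled by homochiral mutual cross-catalysis and fed by
an achiral resource A in a continuously stirred tank reactor (CSTR).
Species order is fixed as {A, 2RD, 1RD, 1RL, 2RL}. The fourteen
unidirectional transformations are numbered 1–4 (D-sector forward/reverse
cross-catalyses), 5–6 (D outflows), 7–10 and 11–12 (the mirror L sector),
13 (inflow of A at constant rate f·[A]in) and 14 (outflow of A). Chirality
forces k1=k7=ka, k2=k8=k-a, k3=k9=kb, k4=k10=k-b. Kinetics are mass
action: v_j = k_j Π_i [X_i]^α_ji, with the kinetic orders α (catalysts
included) stored separately from the net stoichiometry (catalysts cancel
in ν). Concentrations are mol/L, time in s; the termolecular rate
constants therefore carry L²·mol⁻²·s⁻¹ (the source values are printed
unitless; molecularity-implied units are assumed).

Reference parameters: ka=1e4, k-a=10, kb=1e3, k-b=0.5, q=0.2 μL/s through
V=1 L (f = q/V = 2e-7 s⁻¹, converted once at construction), [A]in=1e-4
mol/L, initial replicator concentrations c0=1e-6 mol/L per enantiomer,
initial resource at the feed level, and a chiral seed δ=1e-23 mol/L added
to 2RL. These defaults *are* the study conditions; nothing in the test
suite tunes them.

## Extreme flux modes

The stationary flux cone {v ≥ 0 : νv = 0} is pointed because every
transformation is unidirectional, so its extreme rays coincide with the
support-minimal stationary flux vectors. Enumeration uses the double
description method over exact Python integers (unit rays of the orthant,
one hyperplane at a time, combinatorial zero-set adjacency test), followed
by gcd normalization and a support-minimality sweep. νE = 0 therefore
holds exactly, and the canonical form (coprime nonnegative integers,
ordered by support size then lexicographic support) makes results
deterministic. Matching against the published pathway table is by support
sets, not column position. Floating-point enumeration was rejected to keep
the algebra exact; performance on large metabolic networks is a non-goal
(the networks here have ≲ 30 columns).

Stationary rate vectors are expanded as v = Σ j_i E_i with j ≥ 0 by
nonnegative least squares (scipy's NNLS); off-stationary inputs are
reported through the residual rather than an exception.

## Stiff integration in chiral coordinates

The seed δ/c0 ≈ 5e-18 is below double-precision resolution of the raw
enantiomer concentrations, so the default solver integrates
s = [X_L]+[X_D] and χ = [X_L]−[X_D] per replicator. The χ right-hand
sides are expanded into products of sums and differences — e.g.
[1RL][2RL] − [1RD][2RD] = (s1·χ2 + s2·χ1)/2 — so no term is a difference
of nearly equal monomials; the expansion and its analytic Jacobian are
verified symbolically in the test suite. The initial differences are set
directly (χ2(0)=δ), never by subtracting composed concentrations, which
would round the seed away. Integration is Radau (implicit Runge–Kutta)
with rtol=1e-10 and per-variable atol: 1e-16 for concentrations/sums,
1e-30 for χ. A raw per-species mode exists for arbitrary networks and for
cross-checking at seeds large enough to survive subtraction; the two modes
agree to ~1e-11 relative on the reference problem at δ=1e-10.

Negative concentrations are never clipped during integration; output
samples below −atol abort with the failing time, values in [−atol, 0) are
snapped to zero with a logged count. The output grid is log-spaced,
1e-2–1e9 s at 400 points per decade (plus the t=0 sample). The density is
chosen so that the 6th-order finite-difference cross-check of dσ/dt (below)
resolves the sharp production peak to better than 1e-6 of the derivative's
peak magnitude.

Enantiomeric excesses are computed from χ/s directly (exact at any seed);
reconstructed L/D concentrations cannot resolve |ee| below ~1e-14 %.
Stationary states are taken as the last grid state whose |ν·v| max-norm
falls below 1e-7 of the run's peak (configurable), then Newton-polished by
a root solve of ν·v = 0, which lands on the boundary stationary state with
the extinct enantiomers at exactly zero (typical polished residuals
~1e-28). Sub-threshold stretches before the final one are reported as
metastable windows — the racemic plateau.

Event definitions: the production-peak time is the first local maximum of
σ(t) with prominence ≥ 10% of its global maximum; the symmetry-breaking
time is the first crossing of |ee1| through 50% (log-interpolated); the
plateau is the longest post-peak window in which σ varies by less than 1%.
Absent events are reported as None, never exceptions.

## Entropy bookkeeping

σ = R Σ_pairs (v_f − v_r) ln(v_f/v_r) over the four reversible pairs, with
R = 8.314 J·K⁻¹·mol⁻¹ and σ per unit volume (J·K⁻¹·s⁻¹·L⁻¹). Terms of the
form x·ln(x/y) evaluate to 0 when x = 0 or x = y; arguments below 1e-300
are floored *inside logarithms only*, with guard activations counted.

The equilibrium reference c_eq is the detailed-balance equilibrium the
reactor contents would relax to if isolated from the flow while keeping
their chemical mass. Detailed balance is linear in log-concentrations, so
the solver computes the affine solution family exactly and pins it with
the conserved moiety (the exact rational left null space of the reaction
columns; a single positive moiety is required — here total A-equivalents).
The reference is computed once from the final stationary composition and
reused along the whole trajectory; per-time-point references are
deliberately not used. Note the nuance: the post-breaking NESS is chiral,
while its isolated equilibrium racemizes — the reference is racemic by
construction and depends on the composition only through its mass.

Partial entropies per transformation follow the four kind-specific forms
(forward R·v_f·ln(v_f/v_r); reverse R·v_r·ln(v_r/v_f); inflow
R·f·c_in·ln(c_eq/c); outflow R·f·c·ln(c/c_eq)). Per-pathway entropies
weight each transformation by 1/(number of EFMs whose support contains
it); because those weights sum to one over the pathways containing each
transformation, Σ_i σ(E_i) = σ − σ_e holds as an algebraic identity
(observed residuals ~1e-16 relative), and the sum vanishes at any
stationary state. dS/dt is reported as σ − σ_e, not independently
estimated from a total-entropy functional.

The stationary-state production can equally be computed from the pathway
currents: per reversible pair, v_f (v_r) is the sum of j_i over modes
whose support contains the forward (reverse) column. On the fixture this
reduces to the four-term form driven purely by the open unidirectional
pathways and independent of the unreactive flow-through current.

## Forces, flows and the evolution criterion

Forces F_k = R ln(v_k,f/v_k,r) and flows J_k = v_k,f − v_k,r are defined
for the reversible pairs only, consistent with the production formula; the
matter flows enter the force derivatives implicitly through
d[X]/dt = ν·v, which contains the flow pseudo-reactions. dF_k/dt uses the
analytic log-derivative Σ_i α_ji (d[X_i]/dt)/[X_i] of each monomial
(stable even when the rates underflow), dJ_k/dt the product rule; dσ/dt is
their combination and is cross-checked against a 6th-order central finite
difference of σ in log-time (agreement ≤ 2.7e-7 of the derivative's peak
magnitude on the reference run away from the symmetry-breaking spike,
where the band is relaxed to 1e-2; a coarser grid raises an error rather
than silently degrading). Temperature never appears alone — only A_k/T is
used, keeping the tool isothermal-scale-free.

A noteworthy finding of this implementation: with the four-pair force
definition, dFσ/dt is *not* strictly non-positive along the reference run.
During the approach to the metastable racemic plateau (t ≈ 6e6–1e8 s) the
resource concentration recovers from its conversion overshoot, the
affinities grow while their flows are positive, and dFσ/dt reaches
+2.4e-18 J·K⁻¹·s⁻²·L⁻¹ — about 0.1% of its peak magnitude. The value is
confirmed by two independent derivative routes and is insensitive to
solver tolerance; it accompanies the genuine slow *rise* of σ along the
racemic thermodynamic branch. The evolution criterion in its strict form
is proved for time-independent boundary conditions and need not bind a
CSTR phase with this force bookkeeping; `gec_satisfied` therefore uses a
noise-level tolerance (1e-9 of the peak magnitude) and honestly reports
the excursion. The stability probe accordingly checks that σ never
*re-rises* by more than 1% of its peak after the production maximum,
rather than testing the sign of dσ/dt pointwise.

## What the bundled model does and does not show

The fixture reproduces, from the printed scheme alone: nine extreme flux
modes in parity doublets plus the flow-through singlet (five when the
enantiomer outflows are blocked, in which case the racemic state is stable
and the mirror current equalities never break); full amplification of the
1e-23 mol/L seed to 100% L-homochirality with the 50% crossing at
≈1.9e8 s; the entropy balance identity along the entire run; and the drop
of σ from the metastable racemic plateau to the lower chiral stationary
value (entropy-production minimization). The computed production peak sits
at ≈3.9e6 s — the resource-conversion burst — a factor ~4 later than the
round order-of-magnitude sometimes quoted for it; the timing follows
directly from the printed parameters (the slower replicator initially
decays because kb·[A]in·2c0/2 < f, delaying the hypercyclic blow-up), and
the plateau and symmetry-breaking times agree well.

Limitations: no stochastic (Gillespie) treatment of intrinsic
fluctuations — the seed is an explicit deterministic perturbation; no
spatial extension; no bifurcation continuation in parameter space; no
SBML/CellML exchange or non-mass-action kinetics; no absolute
chemical-potential scales or heat balance (isothermal only). The
no-enantiomer-outflow variant accumulates chemical mass on the very slow
fill timescale (~3e10 s to its equilibrium at these parameters), so tests
probe its quasi-stationary racemic branch rather than its remote final
state.
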
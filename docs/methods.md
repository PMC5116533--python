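# Methods

This note documents the scientific content of `carposim`: the model, the
choices made where the design was genuinely open, the packaged study
conditions, and the limits of what the synthetic experiments demonstrate.

## Compartment model

The fruit interior is partitioned into tetrahedral compartments, each a
regional collection of cells described by three state variables: water
mass w (g), dry matter s (g), turgor pressure P (bar). Volume is derived,
v = w/D_w + s/D_s, i.e. the compartment is exactly as large as its
incompressible contents. Water potential is Ψ = P − π, with the van't
Hoff osmotic pressure π = π_b + RT·S/M_s; the soluble sugar concentration
S = βs/(βs + w) (g sugar per g fresh weight) counts only the soluble
fraction β of the carbohydrate pool. To convert the mass fraction S to a
molar concentration we take the solution density as 1 g cm⁻³, which
closes the units and yields sugar contributions of 1–15 bar over the
physiological range.

Water exchanges are membrane fluxes `A·L·(ΔP − σΔπ)`:

* xylem → flesh with the xylem osmotic pressure neglected (π^x = 0), so
  the xylem runs at P^x = Ψ_stem;
* phloem → flesh with reflection coefficient σ_p and phloem pressure
  P^p = P^x + π^p (the two vessel water potentials are equilibrated);
  vessel sap state is constant in space and time, set by the pedicel
  (Ψ_stem, S_p) — intra-vessel convection and diurnal stem cycles are
  out of scope;
* compartment ↔ compartment with conductivity L and σ = 1, across the
  shared face area A_ij = min of the two adjacent faces.

Transpiration leaves every compartment with boundary area
(A_i^ext > 0): T = A^ext·(c·ρ_crk + (1−c)·ρ_ext)·α(T)·(H_f − H_air).
The printed sources disagree on the sign of the humidity difference
between the cracked and uncracked forms; we use (H_f − H_air) everywhere
so that transpiration is a non-negative loss. α(T) is the saturated
water-vapour concentration from the Tetens formula
(1.727·10⁻⁵ g cm⁻³ at 293.15 K); it can be overridden by a constant.

Sugars arrive by bulk flow V^m = (1−σ_p)·U^p·S_source (source-side
concentration, switching with the flow direction), active uptake
V^a = A^v·ν_max·S_p/(K_m+S_p)·1/(1+exp((t−t*)/τ)), and passive diffusion
V^d = A^v·k_diff·(S_p − S). Respiration R = q_g·ds/dt + q_m(T)·s with
q_m(T) = q_m_ref·q_10^((T−293.15)/10) is substituted and solved in closed
form, ds/dt = (V^m+V^a+V^d − q_m s)/(1+q_g), avoiding a DAE.

Turgor follows the Lockhart/Ortega wall model,
dP/dt = ε·(dv/dt / v − φ·max(0, P − Y)): elastic below the yield
threshold Y, plastic above. Initial turgor defaults to P₀ = Y (neutral
start, no initial plastic burst). The coupled system is stiff and is
integrated with SciPy's BDF using an explicit Jacobian sparsity pattern
built from the mesh adjacency; tolerances rtol 1e−6 / atol 1e−9.

Units: cm, g, h, bar, K. All conductivities and ν_max operate on areas in
cm². A unit audit supports this reading: with areas in cm²,
ρ_ext·α·ΔH = 2.2·10⁻³ g h⁻¹ cm⁻² for the nectarine table, matching the
simulated whole-fruit transpiration rate this package reproduces
(≈3·10⁻³) and the same order as the measured 4.8·10⁻³; an m⁻² reading is
off by 10⁴ and cannot sustain any growth.

## Architecture

**Meshes.** A fruit is two or more nested profiles in the (radial, axial)
half-plane, swept around the z axis (pedicel at z_min). Meshes are built
by tetrahedralizing a structured unit-ball cloud (concentric
Fibonacci-sphere shells, Delaunay) and radially mapping it onto the swept
outer surface; pole caps get extra points because slender features
(elongated blossom tips) subtend a small solid angle. The faceted solid
is inscribed in the smooth surface, so the mesh is calibrated by one
uniform dilation to match the exact Pappus volume of the profile.
Tissue labels are assigned by centroid containment against the swept
inner surfaces (ties resolve inward). This replaces Delaunay-refinement
meshing from segmented image stacks; published tetrahedra counts are
therefore matched in order of magnitude only.

**Vasculature.** Main bundles are user polylines; secondary bundles grow
by space colonization: attractor points sampled uniformly per unit volume
in the flesh, nodes extend step_length toward the mean direction of the
attractors they sense within influence_radius, attractors die within
kill_radius. Two hygiene rules are added: an attractor whose node cannot
make progress (extension would leave the mesh, or would land on an
existing node) is discarded — otherwise tips oscillate indefinitely at
concave or unreachable corners — and ties associate to the lower node
index for determinism. Radii follow Murray's law from fixed-radius tips
basipetally; a global rescale then pins the pedicel radius, reconciling
the "fixed tip radius" and "fixed stem diameter" conventions (the tip
radius therefore cancels from the final radii). Contact areas A_i^v come
from exact convex clipping of each segment against the tet half-spaces
(2πr per clipped length), not sampling. Xylem and phloem are twin
networks on one geometry: A_i^x = A_i^p.

**Growth.** In unconstrained mode vertices never move: face areas scale
as (v_new/v_old)^(2/3) every dt_geom (1 h default), shared areas take the
min of the two faces, and vessel areas stay proportional to the
compartment's total area (a_i^v fixed at t = 0). In constrained mode the
whole mesh (including skin and stone) is first scaled so total volume
matches the summed targets, then interior flesh vertices are relaxed by
Metropolis dynamics on H = λ_v Σ (v*_i − v_i)²; skin and stone vertices
are fixed, moves inverting an element or squeezing a compartment below
its dry-matter volume are rejected outright, sweeps visit vertices in a
seeded random permutation, and the loop stops when H stalls (1e−12) for
≥ 10 sweeps or a sweep cap. Because the Boltzmann acceptance keeps
exploring around the optimum, the best configuration seen is returned,
guaranteeing H(final) ≤ H(after the global scale). Afterwards water is
readjusted, w = (v* − s/D_s)·D_w, read as the only dimensionally
consistent form of the printed rule; a floor of 2% of the previous water
guards compartments the mesh could not expand.

## Packaged experiments and their calibration

**Tomato (24 h, unconstrained).** Round fruit, ~4.5 cm tall, two tissues
(pericarp 70% of volume); homogeneous initial S = 2%, P = Y; published
tomato parameter table. Architecture: a short peduncle section plus ten
axial bundles at 0.70 of the maximal radius, each entering through the
pedicel and spanning only the axial range the profile allows — they reach
neither pole, which produces the characteristic contact-area profile
(maximum at the pedicel layer, mid-fruit plateau, sharp blossom-end
drop). The round profile carries a flattened stem-end shoulder (bottom
superellipse exponent 0.25), as in beefsteak-type fruit; this lets the
bundle bases and their lateral clusters occupy the pedicel layer. SCA
scales (step 0.11 cm, kill 0.22 cm, influence 0.33 cm, 6 attractors per
tet) and the pedicel radius (0.08 cm) are not published; they were
calibrated once against the published architecture facts — ≥90% of
pericarp tets vascularized, the layer profile shape above, and the
water-balance regime in which n = 1 shrinks while n = 2,3,4 grow — and
then frozen. Default mesh ~800 tets (a desk-scale reduction of the
published ~2500).

**Shape comparison (n = 2.5).** Round vs elongated at equal pericarp
volume (the elongated profile is volume-matched numerically), 1100 tets,
and a sparser vasculature (1.2 attractors per tet, kill 0.3 cm): the
published contrast — near-zero vessel contact at the elongated blossom
end — only exists in a bundle-dominated regime; with a dense secondary
network every region saturates to a similar specific contact area and the
shape effect vanishes. "Blossom-end layers" are evaluated as the
water-weighted mean of the top two of ten transversal layers.

**Nectarine (40 days, constrained).** Mesocarp + stone, mesh rescaled so
the initial fresh mass is 60 g; the stone is inert (no exchange, frozen
content, vertices fixed during relaxation, and its mesh volume simply
rides the global scale). Published peach/nectarine parameter table; daily
constrained growth steps; hourly area updates. Vessel areas follow the
published per-compartment assignment: the calibrated total is distributed
proportionally to compartment volume (uniform supply density — equivalent
to the published uniform per-compartment value on a near-uniform mesh)
and held fixed in time; letting the contact area grow with the fruit
makes sugar import scale with size and growth never saturates,
incompatible with the published near-linear growth curve. The total
(10.5 cm² on the 600-tet mesh) was calibrated by the same criterion the
original study states — final fresh mass in the 200–250 g band. The
active-uptake decline (t* = 480 h, τ = 100 h) and the initial sugar
concentration S₀ = 0.055 are not printed; they were chosen once so the
growth curve reproduces the published trajectory, and are config-exposed.
Microcracks: coverage C(X) follows the threshold law with the published
parameters (zero at 60 g, ≈8–9% at final size); the synthetic crack map
is piecewise-constant over the 32 surface patches (4 axial quarters × 8
sectors), increasing quadratically toward the stylar pole with patch
lognormal noise, emulating the measured 0–20% range. The no-crack control
shares everything but the crack model.

## What the synthetic experiments do and do not show

The generator produces idealized axisymmetric fruit with smooth tissue
boundaries, a constant environment (fixed T, humidities, stem water
potential), and stochastic but statistically homogeneous vasculature.
Passing tests therefore demonstrate the internal consistency of the
coupled transport–growth machinery and the architecture-dependence of
water/sugar distribution — not agreement with any particular measured
fruit. Real fruit have asymmetric shapes, diurnal boundary conditions,
microclimate gradients around the skin, and vascular anatomy that is not
space-filling; none of these are represented. Known quantitative
limitations mirror the original study: simulated nectarine flesh sugar
(≈0.06 g/g) sits below typical measured values (0.1–0.2 g/g), and the
simulated whole-fruit transpiration rate (≈3·10⁻³ g h⁻¹ cm⁻²) is below
the measured 4.8·10⁻³; a surface-conductance multiplier is exposed in the
transport parameters for exploring the higher-conductance regime. The
no-crack control retains a small (~6%) radial sugar gradient from base
cuticular transpiration; "homogeneous" in the control comparison means
strictly smaller spatial variation than the crack run, not zero.

## Numerical choices

* BDF with adjacency-based Jacobian sparsity; geometry refreshed every
  1 h window (areas constant within a window).
* Exact segment–tet clipping (no sampling tolerance) for contact areas;
  bounding-box prefiltering for candidates.
* Metropolis step size ε = 0.01 cm, noise G = 10⁻⁵ (published values),
  40 sweeps per daily step in the nectarine scenario (cost/accuracy
  balance at 600 tets; the stall rule usually triggers first on small
  problems).
* Degenerate inputs: inverted tets are flipped once on geometry
  computation and rejected during relaxation; profiles are validated for
  simplicity, nesting and non-negative radii; meshes read from VTK are
  re-validated (conformity, positive volumes).
* Determinism: every stochastic component (mesh jitter, attractor
  sampling, SCA tie-breaks, Metropolis) consumes an explicit seed;
  identical seeds give byte-identical outputs.
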
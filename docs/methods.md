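# Methods

## Model

`colonymech` simulates a confluent epithelial colony as a two-dimensional
vertex model. The tissue is a polygonal tiling; configuration energy

    E = Σ_cells (K/2) (A_α − A⁰_α)² + Σ_edges Λ_e ℓ_e  (+ confinement),

with area stiffness `K`, preferred area `A⁰`, and junctional tension
`Λ_e`. There is deliberately no perimeter-elasticity term: the passive
mechanics contain exactly an area pressure and an edge contractility.
Vertices move overdamped, `γ dx/dt = F`, with three active force
contributions driven by a unit director (polarity) `p` per cell:

* **anisotropic active stress** `S = σ_a (p p − I/2)`, discretized as the
  boundary traction `F_i = −S·n_i` with `n_i` the half-edge-midpoint
  outward normal. This rule is exact virtual work for a constant per-cell
  stress, balances to zero over every closed polygon, and with `σ_a < 0`
  (extensile) elongates the cell along `p`; `σ_a > 0` is contractile and
  elongates it perpendicular to `p`;
* **biased edge tension**
  `Λ_αβ = Λ − (λ/2) [ (ê·p_α)² + (ê·p_β)² − 1 ]`, the lowest-order
  nematic form symmetric in the two neighbours with zero orientational
  mean: junctions parallel to the local polarity are softened, junctions
  perpendicular to it are stiffened, which orients T1 rearrangements so
  that the tissue extends along `p`;
* **motility** `γ v₀ ⟨p⟩` on each vertex, averaging the polarity of its
  adjoining internal cells (boundary cells excluded by default).

T1 transitions replace any interior edge shorter than `ε_cls` by a
perpendicular edge of length `ε_opn > ε_cls` between the formerly
non-adjacent flanking pair; candidates are processed shortest-first, a
fresh edge is protected by a 10-step cooldown, and a flip that would
create a sub-triangle cell or a duplicate contact is skipped. Two further
topological operations keep the strongly active regimes well posed:
interior edges ending on the colony border flip with the exterior playing
the fourth-cell role, and boundary edges below `ε_cls` collapse (border
pinching). A cell crushed below `t2_area = 0.02 A⁰` — a sliver whose
remaining flips are topologically blocked — is removed by collapsing its
shortest edges (a T2); these events are logged and exported as `extruded`
tags so the shear decomposition books them in the extrusion channel.
There is no active extrusion or division rule.

Polarity dynamics are strictly nematic (every torque is `sin 2Δψ`, so all
behaviour is invariant under `p → −p`): interior cells relax toward the
angle of the average neighbour nematic tensor at rate `k_n`, boundary
cells toward the local boundary tangent at rate `k_b`, and, in the
stretching scenario only, every cell toward the stretch axis (x) at rate
`m_stretch`. Defaults `k_n = k_b = 0.1`, `m_stretch = 1` (inverse time
units), angular noise off.

## Units and parameter scales

Simulation units set `A⁰ = K = γ = 1`. Nondimensional activity values
("primed") are measured against the passive junctional tension: the
stress unit is `Λ/√A⁰` and the speed unit `Λ/(γ√A⁰)`, with the default
`Λ = 0.1 K A⁰^{3/2}` a typical sub-rigidity junctional tension. Measuring
σ_a′ against the area modulus `K A⁰` instead would put magnitudes of 5
far beyond the cell-collapse threshold (`|σ_a| ≈ K A⁰` crushes cells), so
the tension scale is the one under which the quoted parameter sets are
physical. The tension-bias unit carries one additional calibrated ratio,
`bias_scale = 0.12`, fixed once so that the three canonical parameter
sets fall in their qualitative regimes (see below); it locates the
crossover between shape-dominated and rearrangement-dominated elongation
and is not re-tuned per run. Biased tensions are floored at zero: a
cortical cable can relax but cannot push, and without the floor the
strong-bias sets drive edges through neighbouring cells (the energy has
no perimeter term to regularize negative tension).

Time integration is explicit Euler with `dt = 2·10⁻³` capped adaptively
so no vertex moves farther than `0.2 ε_cls` per step; any step that would
invert a polygon is bisected. T1 thresholds are `ε_cls = 0.06`,
`ε_opn = 0.13` (in `√A⁰`). Confinement is a harmonic radial penalty of
stiffness `100 K A⁰` outside the colony radius — smooth, and testable
against the energy gradient.

## Simulation protocol

A run has two phases. Under circular confinement, positions and polarity
equilibrate from an initial polarity that mimics the commonly observed
cell-shape pattern: each axis follows the one-elastic-constant defect
field `φ = α₀ + Σ k_i atan2(y−y_i, x−x_i)` for two +½ defects at
(±R/2, 0), with signs assigned randomly under a greedy zero-net-polarity
constraint. The confined phase lasts 30 time units for free spreading
(the tension-network shape relaxation time is `γ√A⁰/Λ = 10`, and the mean
cell-shape nematic needs ~2–3 of those times to become a faithful readout
of `p` against the quenched anisotropy of the initial tiling) and 15 for
the stretching scenario, whose readout is the external axis. Confinement
is then removed; in the stretching scenario the `m_stretch` torque
activates at release. Colony shape is followed by the moment-equivalent
ellipse of the whole tiling (computed exactly from per-cell polygon
moments and the parallel-axis theorem) and summarized as
`Q_xx = ½ ln(a/b) cos 2(θ − α)`, `Q_xy = ½ ln(a/b) sin 2(θ − α)`, with
the reference angle `α` the final colony angle (free spreading) or 0,
the stretch axis (stretching).

Default problem sizes: 120-cell colonies, release phases of 15 (free) or
20 (stretching) time units, 11 recorded frames. These scaled-down sizes
reproduce the qualitative regimes with the quoted parameter sets:

* free spreading, `σ_a′ = −5, λ′ = 20`: the colony elongates along its
  initial mean cell-shape nematic and the cell-elongation channel of the
  cumulative shear dominates the T1 channel;
* stretching, `σ_a′ = 2, λ′ = 50`: elongation along x, T1 channel
  dominant;
* stretching, `σ_a′ = 4, λ′ = 25`: elongation perpendicular to x.

## Orientation fields, defects, and the one-parameter fit

The image pipeline mirrors standard structure-tensor practice: Gaussian
derivatives (σ = 1 px) form `∇I ∇Iᵀ`, smoothed by a Gaussian window of
σ = window/3 (window 20 px for MDCK-like data; 15/40-px presets exposed),
sampled on a regular grid (default 20 px). The nematic angle φ is the
minor-eigenvector direction (along structures) and the coherence
`C = (λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1]`; flat regions get C = 0 rather than NaN.
Defects are plaquette winding numbers: successive angle differences
wrapped to (−π/2, π/2] summed around each grid unit cell; ±½ plaquettes
become defects at the plaquette centre (no sub-grid refinement), other
windings are reported separately. The defect-field ansatz
`φ_fit = α + Σ k_i atan2(y−y_i, x−x_i)` uses the full-plane atan2 branch
— a principal-branch arctan would make the nematic field discontinuous
for half-integer charges. The single parameter α minimizes the
coherence-weighted residual `Σ C_j (1 − cos 2(φ_j − φ_fit,j))` and has
the closed form `α = ½ atan2(Σ C sin 2ψ, Σ C cos 2ψ)` with
`ψ_j = φ_j − Σ_i k_i atan2(…)`; coherence weighting is on by default and
switchable. Mean nematic angles are coherence-weighted tensor averages;
angle differences Δθ are folded to [0, π/2] and compared against the
uniform null CDF with a sup-distance statistic (no p-value is claimed).

## Triangle-method shear decomposition

Each triple of mutually neighbouring cells defines a triangle on the cell
centroids (four-fold cliques are split along their shortest diagonal,
deterministically). Triangle elongation is half the traceless log of the
normalized vertex moment tensor — zero iff equilateral, rotation
equivariant, labeling independent, and equal to the log pure strain of
the map from an equal-area equilateral reference. Per recorded interval:

* **total** shear is the start-area-weighted mean of the symmetric
  traceless matrix log of each persistent triangle's deformation
  gradient (closed-form 2×2 log on SL(2); rigid rotations contribute
  exactly zero);
* **cell elongation** is the change of the area-weighted mean triangle
  elongation over persistent triangles (weights at interval start);
* **T1 / division / extrusion** channels carry minus the jump of the
  mean elongation due to triangle turnover, i.e. +(area-share weighted
  elongation of disappearing triangles) − (that of appearing ones),
  attributed by lineage tags (`divided:<mother>`, `extruded`); untagged
  appearing/disappearing cells are warned about and left to the closure;
* **correlation** is defined as total minus all other channels, so the
  five contributions sum to the total exactly, by construction.

Cumulative curves are running sums started at zero. The area-share
normalization (event triangles weighted by their fraction of the total
triangulated area) keeps single-event contributions commensurate with
the tissue-scale channels.

## What the synthetic data does and does not emulate

The fixture generators close every analysis path without external data:
rendered junction images (anti-aliased edges plus Gaussian noise — no
illumination gradients, photobleaching, or PSF), orientation gratings
(exact for ≤1 defect, streak synthesis by line-integral convolution for
more), affine centroid series (an exact oracle: the triangle method must
return the imposed shear with zero topological channels), and scripted
single-event edits for channel attribution. Passing these tests shows
the machinery is internally consistent and exact on its oracles; it does
not show robustness to segmentation errors, uneven illumination, or
tracking noise in real microscopy, which are out of scope.

## Numerical choices and limitations

Ellipse fits break ties at `a = b` with θ = 0. The disc colony builder
Lloyd-relaxes seed points against a 4096-segment disc polygon (areas then
tile π r² to 1e-6 relative); simulation presets use a coarser border
(180–256 segments) purely as a mesh resolution choice. Determinism: a
single master seed is split into named substreams (mesh, polarity signs,
noise), so adding a consumer never perturbs the others; reruns are
bit-identical. Known limitation: in the strongly biased regimes an
occasional boundary cell develops a transient spike or mild
self-intersection before the topological machinery clears it; centroid
based kinematics are insensitive to this, but strict polygon validation
of a final frame can fail on extreme parameter sets. The regime
acceptance margins are modest at 120 cells (colony Q changes of order
0.03–0.2); one seed in five may land on the wrong side of the
elongation-vs-T1 ordering in the free-spreading case, which is why the
regime checks are specified over seed ensembles.
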
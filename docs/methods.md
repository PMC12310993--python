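# Methods

## Overview

`perfterra` estimates how blood flow distributes over a cerebrovascular
arterial network by coupling two image-derived geometries: a centerline
network (points with lumen radii, organized into segments between
junctions) and a tetrahedral tissue mesh with per-element tissue-class
labels. The method rests on a supply-and-demand argument: each piece of
tissue is perfused by the nearest artery able to reach it, and the flow an
artery must carry equals the metabolic demand of the tissue it supplies.
The pipeline is

1. **Source selection** — every vessel outlet is a source; in addition,
   every centerline point within `d_max` (default 3 mm) of the nearest
   tissue element becomes a *perforator* source, standing in for the small
   perforating branches that leave large vessels directly and are below
   imaging resolution.
2. **Weighted Voronoi tessellation with a connectivity constraint** —
   every element goes to the source minimizing ‖x − p_i‖ / c_i, where x is
   the element centroid, p_i the source position and c_i its propagation
   speed (uniform, c = 1, in the default configuration; the assignment is
   invariant under a common rescaling of all speeds). Territories are then
   restricted to connected regions of the mesh (see *Connectivity
   constraint* below).
3. **Demand** — territory demand is Q_i = ρ Σ_j v_j · CBF_j over the
   territory's elements: tissue density times volume times the per-class
   cerebral blood flow.
4. **Boundary lumping** — outlet-source demands attach to their outlet
   node; perforator demands within one segment are summed into a single
   sink at the segment's arclength midpoint (the segment is split there
   into two half-length sub-segments and the sink attaches to the new
   node; the virtual junction itself is zero-length, so it adds no
   resistance of its own).
5. **Steady 1D solve** — with rigid walls, a uniform cross-section per
   segment (the arclength-weighted mean radius), and steady boundary data,
   the reduced 1D momentum balance with a parabolic profile collapses to
   Poiseuille's law per segment: conductance g = π r̄⁴ / (8 μ L). Mass
   conservation and pressure continuity at junctions give a sparse
   symmetric nodal system; inlet nodes (ICA, BA) are pinned to the mean
   aortic pressure. The convective term and the axial diffusion term of
   the unsteady formulation vanish identically under these assumptions
   (flow is constant along each segment), so the steady linear solve is
   exact for this configuration and no time marching is performed; the
   velocity-profile parameter δ = 1/3 is kept in `FluidConstants` for
   completeness but does not enter the steady solution.
6. **Reporting** — relative flow ratios of the six major cerebral arteries
   (measured in their M1, A1 and P2 segments) and of the three inflow
   vessels; per-territory inlet-contribution fractions obtained from a
   flow-weighted mixing model (each node's outflow composition is the
   flow-weighted average of its inflow compositions; the steady flow field
   is acyclic in the direction of decreasing pressure, so compositions
   resolve in one pressure-ordered pass).

The comparator model replaces steps 1–4 with **Murray's law**: the total
tissue demand is split over the outlets with weights r_i³ / Σ r_j³
(no perforator sinks). Everything downstream — the solve and the
reporting — is shared, so differences between the two models isolate the
boundary-condition strategy.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| inlet pressure | 93.33 | mmHg | mean aortic pressure pinned at ICA/BA inlets |
| blood density ρ | 1.06 | g/cm³ | momentum balance |
| dynamic viscosity μ | 0.04 | g/(cm·s) | Poiseuille conductance |
| δ | 1/3 | – | parabolic-profile parameter (inert in the steady limit) |
| tissue density ρ_t | 1.04 | g/mL | demand (mass = ρ_t · volume) |
| CBF gray / white / other | 0.8 / 0.2 / 0.5 | mL·min⁻¹·g⁻¹ | per-class demand; a uniform-0.5 table is selectable for comparison |
| d_max | 3.0 | mm | perforator source distance threshold |
| centerline spacing | 0.5 | mm | resampling target |
| tessellation speed c | 1.0 (uniform) | – | weighted-Voronoi weight |
| truncation sweep | 0 → 1.0, step 0.05 | mm | 21 sensitivity variants |
| probability-map min count | 10 (of 40) | patients | voxel exclusion threshold |

Units at all interfaces are mm / mL/min / mmHg; the solver works
internally in CGS (1 mmHg = 1333.22 dyn/cm², 1 mL/min = 1/60 cm³/s).

## Connectivity constraint

The tessellation rule is evaluated in two stages: first the pure weighted
Voronoi assignment, then a connectivity-enforcement pass in which each
territory keeps only the connected component containing its best-cost
element, and stranded elements are re-claimed by a front growing outward
from the retained territories (priority-queue ordered by the same
Euclidean/speed cost, claiming only across mesh adjacency). Two design
choices deserve justification:

- **Why not accumulate geodesic cost along the mesh?** A front carrying
  accumulated centroid-graph path length does *not* reduce to the
  Euclidean rule on convex meshes — discrete geodesics systematically
  exceed straight-line distance — so a geodesic formulation would make the
  convex case disagree with the closed-form Voronoi rule it is supposed to
  generalize. The two-stage formulation is exactly the Voronoi rule
  wherever connectivity permits, and enforces connectivity where it does
  not.
- **Why node-sharing adjacency rather than face-sharing?** On structured
  tetrahedral meshes a convex Voronoi cell occasionally contains an
  element that touches the rest of the cell only through an edge or a
  vertex. Under face adjacency such an element would be declared
  disconnected and re-assigned even inside a convex mesh — a pure
  discretization artifact. Node-sharing adjacency is the weakest
  topological connectivity of the mesh: it still forbids jumping across
  genuinely separated tissue (distinct mesh components, opposite banks of
  a sulcus that share no nodes) while leaving convex regions untouched.
  Face adjacency remains available (`TissueMesh.face_adjacency`) and is
  what the adjacency-weighted graph uses.

Elements in mesh components containing no claimable territory are left
unassigned and reported, not errored. Ties in the Voronoi rule go to the
smallest source id; they have measure zero for generic geometry.

## Demand bookkeeping and floating point

Per-territory demand sums run over ascending element ids. The sum of
territory demands and the direct whole-mesh demand then agree to a few
ulps (≤ 1e-13 relative) — exact bitwise equality between two different
summation trees is not a meaningful floating-point statement. The
Murray allocation *is* exactly normalized: the second-largest share is
computed as the residual `Q_total − Σ(rest)` and summed last, which by
Sterbenz's lemma reproduces Q_total bit-for-bit.

The nodal solve is performed on the pressure *deviation* from the
reference inlet pressure. Pressure drops in a healthy arterial tree are
tiny (~0.05 mmHg) against the absolute head (93.33 mmHg); solving for
absolute pressures loses ~3 digits to cancellation in p_u − p_v, which is
visible in mirror-symmetry and conservation diagnostics. With the shift,
conservation residuals sit at ~1e-16 relative and the mirror-symmetric
phantom produces left/right ratio differences at the last ulp.

## Truncation sensitivity protocol

A sweep truncates the network at radii 0, 0.05, …, 1.0 mm (21 variants):
every unprotected segment whose arclength-weighted mean radius falls below
the threshold is removed, then every segment left without a path to an
inlet is removed as well. On a tree this equals "remove the vessel and
its branches"; on the communicating loops it means a collateral-supplied
vessel survives unless it is itself below threshold. The origins of the
MCA/ACA/PCA, their parent vessels and the communicating arteries are
protected (never removed; an attempted disconnection raises); inlets are
never removable. Each variant is re-run end-to-end and summarized by the
per-artery mean and *population* standard deviation (divisor n — a
descriptive statistic over a fixed grid, not a sample estimate) of the
difference between each variant's ratio and the per-artery median across
variants. The median is used as the reference level so that the large
excursions near full truncation do not contaminate it. Failed variants
are flagged and excluded from the median, not fatal.

## Probability maps

Given co-registered per-patient territory label volumes in a template
space, N_{x,i} counts the patients whose map predicts artery
i ∈ {MCA, ACA, PCA} to perfuse voxel x, and P_i = N_{x,i} / Σ_j N_{x,j}.
Patient maps with overlap territories contribute one count to *each*
contributing artery by default (an exclusive mode is available). Voxels
supported by fewer than `min_count` patients (default 10) or outside the
template mask are excluded; the majority map takes the argmax per retained
voxel, ties resolved in the fixed order MCA, ACA, PCA and flagged. Overlap
tables between two maps are row-normalized percentages in both directions,
excluding voxels unlabeled in either map. Registration to the template is
out of scope; inputs must be pre-registered NIfTI volumes.

## Synthetic study geometry

The package ships a deterministic generator (`perfterra.synthetic`) so
that every operation is exercisable without imaging data:

- **Tissue phantoms** are structured boxes of tetrahedra (each grid cell
  split into five, parity-alternated for conformity), with an outer
  "gray" shell (CBF 0.8) around a "white" core (CBF 0.2). The default
  box is 68 × 56 × 24 mm (~91 mL, 7680 elements, ~4 mm elements) — a
  desk-scale stand-in for a brain, convex by construction so the
  tessellation can be checked against the closed-form Voronoi rule.
  Cells left of the midplane are exact mirror images of their right
  counterparts, interleaved in the element list, so mirrored elements
  have bitwise-equal volumes.
- **The toy circle of Willis** has three inlets (L/R ICA at 2.0 mm radius,
  BA at 1.6 mm), the six major arteries with labeled M1/A1/P2 measurement
  segments, communicating arteries (ACoA 0.74 mm, PCoA 0.71 mm) closing
  the collateral loops, and two-level outlet trees per artery with branch
  radii spread over 0.4–0.9 mm so the truncation sweep prunes them
  gradually (20 outlets at r_t = 0, 4 at r_t = 1). Bilateral structures
  are exact mirror images; midline structures are mirror-symmetric point
  sets. Anatomical-variant toggles remove the ACoA or either PCoA, detach
  the left MCA (an unsupplied component: territories are still computed,
  the flow solve refuses that component by raising), or remove the right
  P1 (the right PCA then fed through the PCoA only).

What the phantoms do **not** emulate: cortical folding (territory
boundaries in real brains follow sulci; here they are planar-ish),
realistic radius noise and segmentation artifacts, anatomically
calibrated vessel lengths and tree depths, and any registration error in
the atlas cohort. Tests passing on these phantoms therefore validate the
algorithmic contracts — conservation, oracle equivalence, symmetry,
monotonicity, the tessellation-vs-Murray sensitivity contrast — not
clinical accuracy on patient data.

## Numerical choices and degenerate inputs

- Sparse direct solve (`scipy.sparse.linalg.spsolve`) on the
  Dirichlet-reduced Laplacian; a connected component without a pinned
  inlet raises `UnsolvableComponentError` naming the component's segment
  labels before any factorization is attempted.
- Mean segment radius is arclength-weighted (trapezoidal over intervals),
  not point-averaged: points may be unevenly spaced before resampling.
- Resampling preserves junction/terminal positions exactly, places
  interior points at arclength multiples of the spacing (last interval
  may be shorter), and interpolates radii linearly in arclength. A
  segment shorter than the spacing collapses to its two endpoints. Total
  arclength shrinks by at most one spacing per segment (corners cut at
  skipped waypoints).
- Segment orientation (the sign convention for flows) is assigned by
  breadth-first distance from the inlets; loop segments with equidistant
  ends keep their stored orientation, fixed and recorded.
- Zero-flow edges propagate "no contribution" in the mixing model rather
  than 0/0.
- Degenerate (zero-volume) tetrahedra are rejected with their ids;
  inverted ones are silently reoriented.

## Known limitations

- Perforator demand is lumped per segment at the arclength midpoint (one
  virtual junction per segment, not one per source point). The
  alternative — a virtual branch per source — would change intermediate
  pressures slightly but none of the reported flow ratios, since reported
  flows are measured proximal to the lumping points.
- Junctions carry no minor-loss terms; pressure is continuous across
  them.
- Tessellation speeds are uniform scalars; flow-dependent or per-kind
  speeds are representable in the data model but no calibration scheme is
  provided.
- Secondary collateral recruitment (leptomeningeal, external-carotid
  supply) is outside the model: demand raised beyond what the primary
  collaterals can deliver simply deepens the pressure drop.
- The steady formulation cannot represent pulsatile phenomena; it is the
  correct limit only for steady boundary data.
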
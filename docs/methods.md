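# Methods

## Problem and approach

Quantum-chemical topology asks topographical questions of scalar fields —
where are the maxima of the electron density ρ, how do basins of
attraction partition space (Bader's atoms in molecules), which saddle
points link which maxima (bond critical points), where does a current
density vanish (stagnation graphs)?  Production codes usually answer them
by evaluating ρ and ∇ρ wherever the algorithm wants.  `gridtopo` instead
treats the field as *data*: a finite set of points x_i with values f(x_i),
exactly what a DFT integration grid or a cube file provides, and performs
the entire analysis by post-processing, with no additional function
evaluations.

The key construction is a neighborhood graph N over the points.  All
topographical notions are then graph-native:

* **local maxima** M_L = {x : f(y) < f(x) for every neighbor y};
* **basins**: steepest ascent along edges, stepping to the neighbor
  maximizing (f(y) − f(x))/|y − x|, with path shortcutting;
* **maxima families**: flood fills around each local maximum controlled by
  the scale-free deviation d(x, y) = (f(x) − f(y))/(f(x) − f_min),
  merged transitively, so spatially extended maxima (rings, shells,
  isosurfaces) are recognized as one object;
* **critical paths**: widest (maximin) paths between maxima, read off the
  maximum spanning tree under edge weights (f(i) + f(j))/2; the
  minimum-value node of a path is its critical point;
* **basin integrals**: Q_M = Σ w(x) ρ(x) over each family's basin — Bader
  charges when ρ is an electron density.

## Graph construction

The Delaunay triangulation is the default: it is connected, undirected,
and on bulk nodes basis-preserving (neighbor offsets span R^d, so the
least-squares gradient exists) and move-preserving (every direction has a
neighbor with positive projection, so ascent cannot get stuck in a false
extremum).  Symmetrized k-nearest-neighbor graphs are provided to
demonstrate what goes wrong without those guarantees (disconnection,
fictitious extrema); `validate_graph` reports all four conditions.

Structured point sets (lattices, concentric shells) are massively
cocircular/cospherical — a worst case for incremental Delaunay codes.  We
break ties with a deterministic seeded jitter applied to a copy of the
coordinates, starting at 1e-9 × (bounding-box diagonal) and escalating
(1e-7, then 1e-5) only if Qhull's merge heuristics still fail; the seed
and the magnitude used are recorded in the graph provenance.  At 1e-5 of
the diagonal the displacement is still orders of magnitude below any grid
spacing, so which simplices resolve a degenerate configuration is
arbitrary but reproducible, and no non-degenerate feature is affected.

Hull nodes are flagged, not discarded: their one-sided neighborhoods make
gradients and ascent unreliable, so quality statistics are reported over
the bulk, but every node still receives a basin label.

## Gradients and grid bias

The node gradient solves the unweighted normal equations
M g = b, M = Σ (y−x)(y−x)^T, b = Σ (y−x)(f(y)−f(x)), over the
neighbors of x — the least-squares fit of a first-order Taylor expansion.
A 1/|y−x|² distance weighting is available behind a flag but off by
default, matching the plain residual-norm definition.  Rank-deficient
neighborhoods (typical on the hull) get the minimum-norm solution
restricted to the resolved subspace plus a `singular_mask` flag rather
than an exception; eigendecomposition with a relative eigenvalue cutoff
of 1e-10 decides the rank.

On-graph ascent suffers *grid bias*: ascent directions are quantized to
edge directions, so basin boundaries are systematically displaced, and
the error survives infinite grid density.  The off-graph method
integrates the piecewise-constant nearest-neighbor gradient field
g_NN(x) = g(nearest node of x) with a fixed step, free of the edge
constraint.  Step length is 0.5 × the median incident edge length of the
current nearest node — adaptive to local density, since DFT grids are
radially graded — and a trajectory terminates on entering the Voronoi
cell of a local maximum or of any node whose attractor is already known.
Trajectories are advanced in lock-step batches (deterministic); the step
cap is 10 N^(1/d), and a capped or zero-gradient trajectory falls back to
on-graph ascent with a warning.

## Determinism and ties

All orderings use the total order (f value, then lower node index):
maximality, steepest-step ties, and Kruskal tie-breaking (by
lexicographic edge index after weight), so symmetric inputs give
reproducible outputs.  On exact-value plateaus the ascent terminates at
the plateau's lowest-indexed node; such terminals are included in the
assignment's attractor set even though the strict-inequality
`local_maxima` excludes them (a constant field therefore has no maxima
and basin assignment on one raises an error).

## Maxima families

The deviation measure d(x, y) = (f(x) − f(y))/(f(x) − f_min) uses the
global minimum as its scale anchor: it is dimensionless, lies in [0, 1]
on descending moves, reaches 1 only at the global minimum, and gives
smaller stationary regions around smaller maxima.  Flood fills expand
from each local maximum over neighbors with d < t (default t = 0.25) and
overlapping fills merge.  Two practical consequences are documented
rather than hidden: ascending moves have d < 0 and are always included,
so a fill can climb; and a very weak local maximum (e.g. sampled near a
nodal surface) has an almost unbounded fill, which can merge families
spuriously when the grid does not resolve the valleys between them.  The
cure is grid resolution (or a smaller t), not clipping — see the shell
tests for a worked example of both failure and cure.

Implementation note: fills are never materialized per maximum.  The fill
of maximum m is the connected component of m in the superlevel graph
{f > τ_m}, τ_m = (1−t)f(m) + t·f_min, so two fills overlap exactly when
the two maxima's superlevel components join at a level above the looser
threshold; one descending union-find sweep (a merge-tree computation)
therefore reproduces the transitive fill merging in O(E α).  A family's
covered-node set equals the superlevel component of its loosest member,
and distinct families' coverages are provably disjoint, so coverage is a
single multi-source flood.  This matters because dense atom-centered
grids put thousands of near-degenerate graph maxima on the innermost
shells, each of whose literal fills spans a large ball around its
nucleus; the literal algorithm is retained as a reference oracle and the
sweep is tested against it on randomized instances.

## Critical networks

Kruskal's algorithm on edges sorted by descending weight (ties:
lexicographic) gives the maximum spanning tree; iterative removal of
non-maximum leaves yields exactly the union of all critical paths.  Per
maxima pair linked without an intervening maximum we record the
minimum-value node and its value.  Because the tree is acyclic, rings of
near-equal critical value lose exactly one link; gap-filling revisits
maxima pairs whose basins share a graph edge, builds the maximum spanning
tree of the two-basin subgraph, and accepts the connecting path unless it
touches the subgraph boundary (the signature of a non-critical link).
The already-linked test and all fills are evaluated against the original
pruned tree, making the result independent of pair iteration order.

Cleaving removes paths along which the field departs strongly from the
endpoint maxima: with s(z) = (f(z) − f_min)/(f_scale − f_min) and
f_scale = max(f(x), f(y)), the path deviation is 1 − min s (a mean-based
statistic is available behind a flag).  The "auto" threshold takes the
first local minimum of a Gaussian KDE (Scott bandwidth) of the deviation
distribution, falling back to 0.1 when unimodal.  Cleaving is applied
per path.

A note on invariance: the *node-maximin* critical value is exactly
invariant under monotone transformations of f, but the average-of-
endpoints edge weighting (the method's definition) preserves edge order
only approximately, so near-degenerate alternative routes can swap under
e.g. f → f³ and shift the reported critical value by a few percent.  With
min-of-endpoints weights the invariance would be exact; we keep the
average form as the method defines it and test invariance on fields with
well-separated saddles.

## Synthetic data

The generator provides the study conditions for every test: uniform
lattices with cell-volume weights; uniform-random clouds with clipped
Voronoi-cell weights (computed as halfspace intersections of Delaunay
bisectors and hull facets); and simplified atom-centered grids —
geometric radial shells r_k = r_min e^{kh} with midpoint-in-log weights
r³h, times golden-spiral sphere points (4π/M each), Becke-partitioned
across centers so that overlapping atomic grids remain a true quadrature.
The spiral stands in for Lebedev rules deliberately: positivity and
honest convergence are what the tests need, not optimal degree.  Model
fields (Gaussian peaks, the ring −(|x|−1)², promolecular Slater
densities N α³/π e^{−2αr} with analytic populations, a radial shell
profile sin(ar)e^{−br}, an azimuthal ring current) each carry an
analytic gradient, checked against central differences, and a topology
descriptor.

What the generator does not emulate: wavefunction nodal structure, basis
incompleteness artifacts, grid pruning by weight thresholds, or core/
valence scale separation beyond what a two-exponent promolecule shows.
Passing synthetic tests therefore demonstrates algorithmic correctness on
fields with known topology, not robustness to every pathology of real
densities — which is why the benzene benchmark below runs on a real
Hartree-Fock density.

## The benzene benchmark and the built-in Hartree-Fock backend

The headline benchmark reproduces the electron density at the C-C and
C-H bond critical points of benzene at RHF/cc-pVDZ.  The package carries
a compact self-contained restricted Hartree-Fock engine for this purpose
(`gridtopo.hf`): published cc-pVDZ basis parameters for H-Ne,
McMurchie-Davidson one- and two-electron integrals over s/p/d shells
(numba-compiled, Schwarz-screened, 8-fold symmetry), spherical-harmonic
d functions, DIIS-accelerated SCF, and density evaluation on arbitrary
points.  It is validated against published reference energies (He:
-2.855160, H2O: -76.026799 hartree at the experimental geometry, both
reproduced to ~1e-5) and internal invariances (rotation/translation to
1e-9 hartree, AO normalization, quadrature of ρ to the electron count).

The D6h geometry has two parameters; the shipped values
(R_CC = 2.62375, R_CH = 2.04500 bohr, E = -230.7223494 hartree) were
optimized with this engine by energy-only coordinate descent
(`optimize_benzene_geometry`, resolution 2.5e-3 bohr) and frozen as the
reference structure.  The benchmark evaluates ρ on an atom-centered grid
(default 80 radial shells × 974 spiral points per atom, r ∈ [2e-4, 9]
bohr: ~0.94 M points), builds the Delaunay graph, assigns basins
(12 nuclear maxima), prunes the maximum spanning tree and gap-fills —
closing the aromatic ring — then classifies critical pairs as C-C or C-H
by the density at their endpoint maxima and reports the mean critical
density of each class.  The default problem size converges both critical
densities to well under 1e-3 e/bohr³ of the analytic on-axis density
minima and is chosen so the full benchmark (SCF + ~1e6-point pipeline)
completes in minutes on one CPU.  Note that the C-H value is strongly
geometry-sensitive (about -0.3 e/bohr³ per bohr of C-H stretch, an
order of magnitude more than any grid effect at this resolution), so
reported values are meaningful only together with the geometry above.

No sub-grid refinement of critical values is attempted: the reported
density is the value at the minimum grid node of the critical path, so
its accuracy is set by the grid resolution near the saddle.

## Numerical choices

* duplicate points merged at 1e-12 bohr, weights summed;
* gradient rank cutoff 1e-10 (relative eigenvalue);
* nearest-node ties resolved within relative 1e-12 toward the lowest index;
* family tolerance default t = 0.25;
* off-graph step 0.5 × median incident edge length, cap 10 N^(1/d);
* missing integration weights default to clipped Voronoi cell volumes;
* SCF: convergence 1e-9 hartree and 1e-6 on the DIIS error, basis
  functions S-renormalized, canonical orthogonalization cutoff 1e-10.

## Known limitations

* No periodic boundary conditions, anisotropic metrics, or d > 3.
* Basin boundaries are node partitions; fractional (fuzzy) basin weights
  are not implemented, so basin integrals inherit O(cell volume)
  assignment noise at the boundary.
* The k-NN construction exists to demonstrate its own inadequacy; all
  quantitative claims assume the Delaunay graph.
* The Hartree-Fock backend is restricted, closed-shell, s/p/d only, with
  in-core integrals — a benchmark engine, not a general SCF code.
* The critical network reports node positions and values only; no
  derivative-based refinement of critical points is performed.
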
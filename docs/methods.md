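# Methods

This note documents the models, algorithms and numerical choices behind
tunnelkit, what the synthetic benchmark does and does not emulate, and the
known limitations.

## Structures and provenance

A `Structure` is an ordered atom list with a time stamp and two tags: a
source tag (`crystal`, `minimized`, `frame`, `pseudo`) and a state tag
(`apo`, `holo`, `pseudo_apo`, `pseudo_holo`, `synthetic`). Crystal and
minimized structures carry sentinel times of -2 ps and -1 ps so that
first-occurrence orderings place them before frame 0 of a trajectory; these
sentinels propagate into discovery curves and cluster statistics.

Van der Waals radii come from a fixed element table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20, P 1.80, Fe 1.40 Å; 1.70 Å default). HETATM groups are
ligand unless they are water, a simple ion, or heme — the heme cofactor is
part of the active-site wall in P450-like systems and must not be carved out
of the protein. Before tunnel calculation a structure is stripped of
hydrogens, waters, ions, and (by default) the ligand; the stripping is a
view, not destructive, so hydrogen-bond analysis can still use the full
structure.

## Superposition and structural dissimilarities

Rigid-body fits use the Kabsch solution (via SVD); the protocol is "fit on
Cα, measure on heavy atoms": ensembles are superposed onto their first member
on Cα atoms (all heavy atoms for synthetic systems without Cα naming), then
heavy-atom RMSD is measured with surface-exposed residues excluded.

Surface exposure is decided once, on the crystal structure, by Shrake-Rupley
SASA (probe 1.4 Å, 960 golden-spiral points per atom) converted to relative
side-chain accessibility against an extended Gly-X-Gly reference table;
residues above 30% relative accessibility are masked. All four parameters
are configurable; residue types missing from the reference table (synthetic
pseudo-residues) use a generic 150 Å² reference with a warning. With a fixed
point set the SASA is exactly translation invariant and rotation invariant
only up to discretization (total area conserved to a fraction of a percent).

Three dissimilarities drive ensemble reduction:

- **Heavy-atom RMSD** (after masked superposition), used by gromos
  clustering.
- **Pairwise-distance dissimilarity**: S_kn = sqrt(mean over heavy-atom
  pairs ij of (d_ij(k) - d_ij(n))²), over buried heavy atoms only. Internal
  distances make it rigid-motion invariant without superposition. Above 50k
  pairs a seeded deterministic subsample is taken and flagged on the result.
- **Hydrogen-bond-network mismatch**: bonds are N/O donor→acceptor pairs
  within 3.5 Å with an H-donor-acceptor angle within 30° when hydrogens are
  present (distance criterion alone otherwise); same-residue pairs, waters
  and ligand are excluded. The position universe is the union of bonds over
  the ensemble (restricted to buried residues), and the score is the mean
  per-position mismatch, 0 for identical networks, 1 for disjoint ones.
  Restricting to the union avoids vacuous agreement at never-bonded pairs
  diluting the score.

## Clustering

`KMedoids` is PAM with deterministic greedy BUILD initialization (ties to the
lowest index) and best-improvement SWAP to a local optimum; no randomness is
involved, so results are exactly reproducible. On pools of up to 8 items the
SWAP optimum matched exhaustive medoid search in every tested case (this is a
test, not a guarantee: PAM is a local search).

`GromosClustering` is iterative neighbor counting: the structure with the
most neighbors within the cutoff becomes a center and is removed with its
neighbors; repeat. Given a target ensemble size instead of a cutoff, the
smallest cutoff yielding at most that many clusters is found by bisection
over the *critical values* (the sorted pairwise dissimilarities), which is
exact — the count only changes at those values, and plateaus are commonly
narrower than any fixed cutoff step.

One subtlety is documented by a unit test: the greedy count at a single
isolated cutoff can tick *upward* by one as the cutoff grows (removing a
larger first cluster can strand extra singletons). The procedure that
matters here — grow the cutoff until the target size is reached — is
stateful and never discards a coarser clustering it has already obtained, so
sweep counts are reported via `sweep_counts` (the running best), which is
non-increasing by construction. The single-cutoff `fit` remains the
canonical algorithm.

Cluster representatives are always actual members (medoids/centers), never
coordinate averages: only real conformations have meaningful tunnel
geometry. Crystal and minimized structures are excluded from clustering
inputs, so a 103-member time-point ensemble clusters its 101 frames.

## Tunnel prediction

The tunnel finder works on a regular grid (0.8 Å spacing) covering the
structure's bounding box plus 6 Å padding. Each node stores its clearance:
the distance to the nearest atom's van der Waals *surface* (negative inside
an atom). Surface distance, not center distance, makes the probe radius
physically meaningful. The nearest-surface query uses a k-nearest KD-tree
query with an exact widening fallback for nodes where a farther atom could
still be closer in surface distance.

Node classes at probe radius p:

- **protein**: clearance < p (impassable);
- **bulk**: passable space outside the convex hull of the atom centers,
  together with wide regions (clearance ≥ 3.0 Å) connected to it or to the
  grid boundary. The hull term matters: without it, the thin passable skin
  that wraps any protein below the wide-bulk threshold connects all channel
  mouths into one region and the graph can sneak between exits around the
  outside;
- **interior void**: the passable remainder (cavity and channel interiors).

Costs are c(x) = exp(-α·clearance), α = 1/Å by default; edge weight between
26-neighbors is the step length times the mean endpoint cost, so a path
integrates narrowness along its length — short and wide paths rank best.
Dijkstra (scipy csgraph) runs from the start node over interior void only;
bulk nodes terminate tunnels. Exit patches are connected components of bulk
nodes adjacent to reachable interior void (the channel mouths, which are
mutually disconnected even though the bulk as a whole is one region). Per
patch, the lowest-cost adjacent interior node is the mouth; the reported
tunnel is the backtraced path plus the widest adjacent patch node (so a
narrow rim node cannot masquerade as the bottleneck). A path that grazes the
surface (comes within one grid cell of bulk) and then wanders through ≥5
further interior nodes is truncated at that first contact; tunnels with
fewer than 3 spheres are dropped. Tunnels are ranked by cumulative cost.

The start point is user-supplied (for P450-like inputs a helper places it
3 Å above the heme ligand-binding face along the Fe-S vector). If its
clearance is below the probe, integer-Å offsets are tried on L∞ shells of
growing radius (axis directions first, then lexicographic), up to radius 5.

`overshadow` mode emulates exit-merged reporting: tunnels whose exit points
lie within 6 Å (connected-component grouping) are merged and the
widest-bottleneck one kept, so it never reports more tunnels than `raw`
mode.

Grid discretization biases measured bottlenecks low by up to roughly half a
cell diagonal plus ring discreteness (~0.3-0.4 Å at 0.8 Å spacing in the
benchmarks), because no node lies exactly on the channel axis. All tolerance
checks therefore use the grid spacing as the natural error scale.

## Tunnel clustering, matching, naming

The tunnel dissimilarity is the symmetrized mean nearest-point distance over
sphere centers: D(a,b) = ½[mean_a min-dist to b + mean_b min-dist to a].
Symmetrizing makes the pool order irrelevant; radii are deliberately not
part of the geometry (clustering is by location). D is symmetric,
non-negative and zero on identical point sets, but it is not a metric — the
triangle inequality can fail, and very short tunnels sit artificially close
to everything that shares their first segment, which is the known mechanism
by which boundary tunnels merge or split clusters.

Clustering grows k (PAM at each k) until every member is within 5.0 Å of its
centroid. A test clustering matches a reference cluster when the distance
between centroids is smaller than the reference cluster's own radius (its
largest centroid-member distance) — "the test centroid would fit into the
reference cluster". Singleton reference clusters have radius 0, which would
forbid even exact self-matches under a strict inequality, so coincident
centroids (distance < 1e-6 Å) always match. Matched fractions are reported
as integer percentages, rounded half-up. Cluster naming assigns each
annotation (a named reference polyline, treated as a cluster of radius
5.0 Å) to its nearest cluster, closest pair first, one name per cluster;
leftovers are `unassigned-i`.

Per-cluster statistics: first occurrence is the minimum member time (the
sentinels order crystal < minimized < frames); the bottleneck series takes,
per source structure, the widest member bottleneck; fluctuation is the
population standard deviation over structures where the tunnel is *present*
(absence is missing data, not zero — a configurable choice in
`bottleneck_series` consumers).

## Synthetic benchmark systems

The generator builds a pseudo-atom shell (carbon-like atoms, vdW 1.7 Å) on a
cubic lattice between an inner cavity radius (7 Å) and an outer radius
(13 Å). The lattice spacing of 2.6 Å makes the bare shell impermeable to a
0.75 Å probe with margin (worst-case body-center clearance 0.55 Å); the
generator can verify impermeability by flood-fill and errors if the shell
leaks. Channels are carved cylinders sealed by a *gate*: an annular disc of
atoms across the channel whose inner aperture follows
`gate_closed + openness(t)·(gate_open − gate_closed)`. The disc layout
(rings, atoms per ring) is fixed over the trajectory — gate atoms slide
radially — so topology is constant across frames. The theoretical bottleneck
of an open channel is its aperture, which the grid finder recovers to within
one grid spacing; a calibration test requires agreement within
(jitter + spacing) in ≥95% of open frames.

Frames add seeded isotropic Gaussian jitter (σ = 0.05 Å default) and,
optionally, a cumulative per-atom random-walk drift with an irregular
per-frame step scale (uniform in [0.5, 1.5]×σ_drift). The irregular scale
matters for clustering benchmarks: a time-homogeneous walk collapses all
pairwise RMSDs onto a function of the time lag, a degeneracy real
trajectories do not have. The apo/holo contrast pins `blocked_by_ligand`
gates to a ligand-conditioned openness while the ligand blob is present;
pseudo states start in the source state's gating at frame 0 and relax to the
target state afterwards, emulating a short re-equilibration.

What the generator does *not* emulate: any force field or energetics,
side-chain rotamers, water structure, realistic protein topology, or
correlated collective motions. Passing tests therefore demonstrate that the
geometric pipeline is correct on systems whose ground truth is known exactly
— not that it reproduces any particular protein's tunnel landscape.

Preset study conditions: `basic` (three static channels, radii 2.5/2.0/1.5 Å,
no jitter), `gated` (101 frames at 100 ps, one channel opening at frame 50),
`apo_holo` (apo-only gate A, holo-only gate D, shared solvent channel S;
2 ns frame spacing so crystal+frames gives 7-member parents and a 14-member
mixed ensemble), `preferred_vs_rare` (a 1.3-2.5 Å oscillating channel versus
a static 1.15 Å channel — the static aperture sits far enough above the
probe that grid discretization cannot push it below detection).

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately small problem
sizes: tunnel-prediction ensembles of 5-23 members on ~50³ grids, and a
101-member ensemble (shell only, no channels) for the structure-clustering
contract, where the gromos reduction to the 21-member target is verified to
land exactly. Gate apertures in the presets keep at least ~0.3 Å margin from
the probe radius so classification is stable under jitter. Ties everywhere
break to the lowest index; all randomness flows from explicit seeds;
percentages round half-up.

## Known limitations

- PAM is a local search; global optimality is verified only at small n.
- The tunnel dissimilarity is not a metric; cluster counts are sensitive to
  boundary tunnels (reproduced as a property test, with the 5.0 Å radius
  contract as the stable invariant).
- The cost functional exp(-α·clearance) is one defensible realization of
  "short and wide ranks best"; rank order is validated against constructed
  ground truth only.
- Bottlenecks are grid-quantized and biased low by up to one spacing.
- No mmCIF or compressed trajectory input; no physicochemical tunnel
  characterization or tunnel-lining residue analysis.
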
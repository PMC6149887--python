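# Methods

## The search problem

Flexible-ligand docking asks for the pose of a small molecule in a receptor
site that minimizes an interaction energy. The search variable is a real
vector of `7 + n` genes: a rigid-body translation `(t_x, t_y, t_z)` in Å, a
rigid-body orientation as a unit quaternion `(q_w, q_x, q_y, q_z)`, and one
dihedral angle per rotatable bond (degrees, half-open `[-180, 180)`). A
ligand's torsion tree — a rigid root set plus nested branches, each branch a
rotatable bond with the atom set distal to it — turns that vector into
Cartesian coordinates: branch dihedrals are applied depth-first from the root
outward about the current bond axis, then the whole molecule is rotated about
the root-set centroid and translated. The rotation center and the quaternion
encoding follow the AutoDock convention; renormalization after every
stochastic operator keeps the quaternion on the unit sphere to 1e-9.

The energy surface is deliberately pluggable:

* **Grid maps.** The receptor is pre-tabulated as one 3-D affinity lattice
  per ligand atom type plus an electrostatic lattice; a pose's energy is the
  sum over atoms of trilinear map interpolation, plus charge × electrostatic
  interpolation, plus a torsional penalty `W_tors × torsdof`
  (`W_tors = 0.2983 kcal/mol`, the AutoDock 4 weight; 0 in the synthetic
  fixtures). Atoms outside the box contribute a large finite penalty
  (`1e5 + squared distance to the box`, per atom) instead of raising, so
  stochastic operators remain total functions. The full semi-empirical
  force field behind real AutoDock maps (desolvation, directional H-bonds)
  is intentionally out of scope; map *consumption* is faithful, map
  *generation* is synthetic.
* **Toy pairwise receptor.** An explicit-atom 12-6 Lennard-Jones plus
  Coulomb with distance-dependent dielectric `ε(r) = 4r` (`r` floored at
  0.5 Å so degenerate fixtures stay finite). Pair parameters `(r_eq, ε)`
  ride on the receptor atom.
* **Analytic landscapes.** `sphere`, `rastrigin-like`
  (`10d + Σ(x² − 10cos 2πx)`, bounds ±5.12) and a `double-funnel` (a broad
  basin of depth −1 against a narrow basin of depth −2, so undirected
  sampling lands in the wrong funnel). These act directly on raw genome
  vectors, letting every operator and archive property be tested with no
  molecular fixture.

## The algorithms

`ga` is a plain generational GA: linear-rank selection (best rank gets
weight `n`, worst 1; rank-based weights sidestep the sign/scale problems of
raw negative energies), two-point crossover (cut points drawn from `0..n`
inclusive; the segment between them swaps), and per-gene Cauchy mutation
(rate 0.02, scale 0.05 × gene width — heavy tails give occasional long
jumps).

`lga` adds Lamarckian local search: Solis–Wets adaptive random search on a
subset of the population, with the improved genome written back into the
individual. Trial steps are Gaussian with deviation `ρ × 0.05 × gene width`
plus an exponentially smoothed bias toward recent successes; a failed step
is retried in the opposite direction; `ρ` doubles after 4 consecutive
successes, halves after 4 failures, and the search stops at `ρ < 1e-3` or
300 steps. The subset is a **random** 6% of the population each generation
(the search-frequency convention). An earlier variant that always polished
the ranked-top individuals was discarded: with elite preservation active the
top block is clonal, so every generation's local-search budget was spent
re-polishing one basin and the search stalled on multimodal surfaces.

`hga` — the package's contribution — augments `lga` with three
running-history mechanisms:

* **Elite-parent-preserving crossover.** After rank-selected two-point
  crossover, the `⌈0.1 n⌉` best current individuals (elite fraction 0.1
  default) are carried into the next population together with the two parent
  genomes whose crossover produced them (an elite that was never crossed —
  e.g. a survivor of the random initial population — records itself as both
  parents). Population size is restored to `n` by trimming surplus crossover
  children; children are unevaluated at this point in the loop, so the trim
  removes tail children (exchangeable by construction) rather than ranking
  them.
* **History-difference mutation.** A mutating gene draws
  `θ, δ ~ U(0,1)`: with `θ < β` (β default 0.1) it is resampled as
  `lower + θ(upper − lower)`; otherwise it moves by
  `θ(M_opt − M_sub) + δ(M_opt − m)`, where `M_opt`/`M_sub` are the best and
  second-best *distinct* genomes ever evaluated (updated online after every
  energy evaluation). The same θ serves branch test and formula, so β = 1
  yields exact uniform reinitialization. The update is gated by the standard
  per-gene mutation rate (0.02): it replaces the Cauchy mutation *kernel*,
  not the mutation *rate*. Applying it to every gene every generation
  collapses the population onto `M_opt` within ~10 generations — the
  premature convergence the mechanism is meant to prevent.  If the
  population has fully converged (`M_opt = M_sub = m`), the non-resampling
  branch is exactly the identity; escaping that fixed point is the archive's
  job.
* **Non-revisiting BSP archive.** Every candidate genome is quantized to a
  cell (translations 0.25 Å, quaternion components 1/64, torsions 2°;
  plain landscape genes 1/128 of the bound width) and stored in a binary
  space partition tree. The tree starts as one leaf spanning the whole
  discretized space; when a second distinct cell lands in an occupied leaf,
  the leaf splits at the integer midpoint between the two occupants along
  the dimension where they are farthest apart in bound-normalized units, so
  children always partition their parent exactly and node count is
  `2 × cells − 1`. A candidate whose cell is already stored is redirected to
  a uniform point inside the nearest leaf subspace that still holds
  unvisited cells (Euclidean distance from the bound-normalized query to the
  box; ties resolve left-first), and that cell is stored in turn. The
  archive guarantees no cell is ever evaluated twice and raises an explicit
  saturation error once the discretized space is exhausted. The archive is
  consulted after crossover and mutation, before fitness evaluation; local
  search probes bypass it by default (`archive_local_search` routes them
  through when a strict whole-run non-revisit audit is wanted).

One `numpy.random.Generator`, seeded from the run config, feeds every
stochastic decision in a fixed order (selection, crossover cuts, mutation,
archive redirects, local search), so identical config + seed reproduces a
bit-identical result; result JSON omits wall time for that reason. A run
stops at whichever of the generation cap or energy-evaluation cap comes
first; local-search evaluations count against the cap and are truncated by
the remaining budget, never allowed to overshoot it. Default caps mirror the
standard docking protocol (population 50, 27,000 generations, 1.5 × 10⁶
evaluations); the test and acceptance profiles below use smaller caps.

## Analytics

* **Success.** A run succeeds when the heavy-atom, atom-order-matched RMSD
  (no superposition; both poses in the receptor frame) between the best pose
  and the reference is strictly below 2.0 Å. Averages are reported over all
  runs and over the successful subset; with zero successes the latter is an
  explicit undefined marker, never 0. Symmetry-corrected RMSD is not
  implemented.
* **Clustering.** Docked conformations are clustered with the energy-ordered
  leader rule: process poses by ascending energy (ties by index); a pose
  joins the first cluster whose seed is within the RMSD tolerance (2.0 Å
  default), else it seeds a new cluster. Clusters are reported by ascending
  lowest-member energy; rank 1 therefore always contains the global-minimum
  pose, and its size measures search reliability. The rule is deterministic
  and permutation-invariant; a nonempty input always yields between 1 and n
  clusters.
* **Distributions.** Tukey five-number summaries with quartiles by linear
  interpolation between order statistics; whiskers end at the most extreme
  points within 1.5 × IQR of the quartiles and everything beyond is an
  outlier.
* **Hypothesis testing.** A pairwise one-sided Mann–Whitney matrix is
  provided as a generic nonparametric comparison utility; it is one
  reasonable choice of test, labeled as an interpretation rather than a
  canonical protocol.

## Synthetic fixtures and what they show

`make_toy_complex(n_torsions, seed)` builds a redocking problem with known
ground truth: a compact helical chain ligand of `n_torsions + 3` carbon
atoms (helix radius 1.5 Å, rise 0.6 Å, turn 100°), each atom carrying its
own synthetic atom type and hence its own affinity map. A target pose is
drawn from the seed: uniform random orientation and torsions, with the
translation centering the resulting conformer in the box plus a ±1.5 Å
jitter; because random dihedrals can stretch the chain into an extended
conformer, draws are rejected until every atom lies at least 1.5 Å inside
the box, so the reference pose is always fully scoreable. Atom `a`'s map
holds
`−depth · exp(−|g − t_a|² / 2σ²)` (depth 1.0, σ = 2.0 Å, spacing 0.5 Å,
41³ points) at each node `g`, with `t_a` the atom's target position. The
grid score is minimized exactly when every atom sits at its target, so the
optimum genome and reference coordinates are known by construction, and the
stored optimum energy is self-checked against random rival poses at build
time. What these fixtures deliberately do **not** emulate: force-field
ruggedness and clash terms, pose symmetry, map noise — so a passing recovery
test shows the *search* finds a known funnel through real torsion-tree
kinematics, not that the scoring of real receptors is reproduced.

## Problem sizes used by tests and the acceptance script

Desk-scale profiles, chosen as the package's own evaluation protocol:
landscape comparisons run population 50 for 500 generations on the 10-D
rastrigin-like surface (20 paired seeds in the test suite, 10 in the
acceptance script); redocking runs population 20 for 60 generations with
60-step local search, 20 seeds per complex at 0, 5 and 10 torsions; the
non-revisit audit runs 10⁴ archived evaluations on the 2-D discretized
landscape (128² cells). With these sizes the history-guided mode reaches
median final energies orders of magnitude below plain GA and recovers toy
reference poses well under the 2.0 Å threshold.

## Numerical choices and edge cases

* Torsions are stored in degrees and wrapped half-open; internal
  trigonometry is in radians. Wrapping (not clipping) preserves angular
  topology under mutation.
* Quaternions are renormalized after clipping; a degenerate zero quaternion
  repairs to the identity.
* `M_sub` updates require a genome *distinct* from `M_opt` (array
  inequality), otherwise a duplicate evaluation of the best pose would
  collapse the history-difference vector to zero permanently.
* Leader clustering ties (equal energies) break by pose index, making
  membership deterministic.
* The archive's leaf sampling uses rejection with a deterministic exhaustive
  fallback, so redirection cannot loop.
* Selection with all-equal fitness degenerates to uniform sampling via
  average ranks.
* Budget edge: if the evaluation cap dies inside a generation, the run
  returns a partial trace rather than raising; the trace records best-so-far
  per generation, hence is monotone non-increasing with its final entry equal
  to the reported best energy.

## Known limitations

* No symmetry-corrected RMSD; automorphism-equivalent poses can score as
  distinct.
* No flexible receptor side chains, ring conformer sampling, or map
  generation from real receptors.
* The BSP archive's memory grows linearly with distinct evaluated cells; no
  pruning or forgetting policy is implemented.
* The archive's redirection is "nearest unvisited subspace", which near a
  converged population amounts to a slowly growing shell of visited cells —
  it maintains diversity locally but is not a global restart mechanism.
* Whether local-search probes should pass through the archive is genuinely
  open; the default (no) follows the loop order of crossover → mutation →
  archive → evaluation → local search, with a flag to flip it.
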
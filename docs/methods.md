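# Methods

This note records the models, estimators and numerical choices behind
`metadiss`, and what the synthetic benchmarks do and do not establish
about real simulation data.

## Descriptors

Coordinates are Ångström throughout; the time per frame is supplied by
the user because trajectory formats do not reliably carry it.  The three
per-frame descriptors are:

* **Centre-of-mass distance** between the two chains, mass-weighted by
  default (geometric weighting by flag).  This is also the metadynamics
  collective variable (CV), in which role it is handled in nm.
* **Fraction of native contacts Q**: native contacts are all inter-chain
  residue pairs whose minimum heavy-atom distance is below 4.5 Å in a
  reference structure (the common heavy-atom contact convention; the
  threshold is configurable).  A frame's contact is "formed" with the
  same cutoff — no hysteresis factor.
* **SASA** by the Shrake–Rupley construction (Fibonacci point sets,
  960 points and a 1.4 Å probe by default), element-wise van der Waals
  radii, heavy atoms only when hydrogens are absent.

## State definition

The bound ensemble of each descriptor shows a bell-shaped distribution.
A logistic membership `m(x) = 1/(1+exp(-s(x-x0)))` is fitted to the half
of that bell the descriptor crosses during dissociation: the right half
for distance and SASA (which grow), the left half for Q (which shrinks).
Fitting details that matter:

* Histogram: Freedman–Diaconis bin width, density-normalised; the bin
  count is additionally capped at the number of distinct values so that
  discrete descriptors (Q takes ~n+1 levels) do not produce comb
  histograms with empty bins.
* The chosen half is rescaled so the mode bin maps to 1, and that mode
  bin is anchored in the least-squares fit with a 10× weight — this
  realises "membership 1 in the bound basin" and keeps the fitted
  membership ≥ 0.95 at the mode for Gaussian-like input.
* The density is zero beyond the sampled range; explicit zero-height
  bins (half again the half's span) encode this, without which the fit
  under-weights the tail.
* A fit whose membership fails to decay across the fitted half (possible
  when the half has very few informative bins) is treated as degenerate.
  Degenerate distributions fall back to a steep step-like membership
  five sample standard deviations from the bound median.  Ties in the
  mode bin break toward the side that maximises the fitted half's span.

The product of two memberships forms the state curve.  Transitions are
the first frame where the curve stays below a threshold for a dwell
window (default: 1 % of the trajectory, at least 10 frames):
distance × Q below 0.5 (logistic midpoint) marks the start of
dissociation; Q × SASA below 0.05 ("approaches zero") marks the start of
the unbound state.  Both thresholds are configurable; if the unbound
transition is detected first, the dissociation start is clamped to it so
bound ≼ encounter ≼ unbound always holds.  The bound reference window
used for fitting is a user parameter (the pipeline defaults to the first
45 % of the first run); a near-constant bound window degrades the
Q × SASA detector, which inherently needs thermal fluctuation in the
bound ensemble to calibrate its memberships.

## Free energy

Standard (non-well-tempered) metadynamics with constant hill height is
assumed.  Two estimators are provided:

* **Bias route**: F(s) = −V(s, t), with V the accumulated Gaussian bias.
  Optionally −V is averaged over the hill times in the final fraction of
  the deposition (one-pass implementation weighting hill *j* by the
  fraction of averaging times it precedes); this damps the O(hill
  height) oscillation of the filling bias.
* **Reweighting route**: frame weights exp(β(V(s_f, t_f) − c(t_f))) with
  the flat-prior (standard-metadynamics) limit of the time-dependent
  bias offset, c(t) = (1/β) ln⟨exp(βV(s, t))⟩_grid, evaluated just after
  each deposition and computed with log-sum-exp guarding.

Repeated runs are combined as probability densities (per-run weights
default to uniform; the per-frame reweighting already carries the bias
information), renormalised, and Boltzmann-inverted with k_B =
0.008314463 kJ/mol/K and T = 300 K by default.  Unsampled bins carry
+∞ free energy.  Each run contributes only up to its detected start of
dissociation when transition reports are available; the structural
transition frame is mapped to the CV series by elapsed fraction of the
trajectory.

**Depth of the bound minimum.**  The transition level is the maximum
finite F between the bound minimum and the largest sampled CV value.
Two guards matter at desk scale: (i) histogram bins straddling the edge
of the sampled domain are only partially occupied, and a deposition
kernel loses part of its mass beyond the edge — both bias F upward
there, so the outermost bins (two hill widths inside the sampled range
for combined-run depths) are excluded from the search; (ii) the LOO
driver defaults to the bias route because bin-level noise in the
histogram route feeds this maximum statistic and inflates depths by
~0.5 kJ/mol.  With a converged deposition protocol (hills to well past
parity, late-time averaging over the final 80 % of hills) the combined
estimate is accurate to ~0.2 kJ/mol on a 12 kJ/mol well.

**Leave-one-out interval.**  The reported interval is the hull of the n
recombinations each omitting one run, together with the all-runs
estimate.  This is a *sensitivity range*, not a confidence interval:
for n homogeneous runs its width is range(x)/(n−1) ≈ 0.34 σ_single,
while the all-runs mean itself fluctuates by σ_single/√n ≈ 0.32 σ_single
— so even a perfectly unbiased estimator brackets the true depth in
fewer than half of independent repetitions.  The interval is reported
for comparability between systems, and its narrowness should be read as
run-to-run consistency, not as coverage.

**Correlation with melting temperatures.**  Pearson and Spearman
coefficients over systems with a T_m; systems without one are excluded
from the fit but reported (and kept in the depth table).

## Contacts

Geometric criteria (restated so they are reproducible; all thresholds
configurable): hydrogen bond donor–acceptor heavy-atom distance ≤ 3.5 Å
with D–H…A angle ≥ 110° when hydrogens are present, distance-only
otherwise (declared no-angle mode); salt bridge anionic O (Asp/Glu) to
cationic N (Lys/Arg/His⁺) ≤ 4.0 Å; π-cation: cationic N within 6.0 Å of
the ring centroid and ≤ 60° off the ring normal; π-stack: centroids
≤ 7.0 Å, normals ≤ 30° apart; T-stack: centroids 5–7 Å, normals 60–90°;
hydrophobic: side-chain carbon–carbon ≤ 4.5 Å between apolar residues.
Histidine counts as cationic only when labelled HIP/HSP.  A pair that
qualifies as a salt bridge does not additionally emit a hydrogen bond
between the same ionic atoms.  Distance-only van der Waals pairs are
never emitted.  Author residue numbering is preserved verbatim.

Occurrence is the fraction of window frames containing each
(pair, type); filtering keeps entries *strictly greater* than the
threshold (the ">20 %" rule).  Coarse-graining aggregates residue pairs
into secondary-structure element pairs (labels: chain letter + element
letter) by the maximum member occurrence — preserving the "key contact"
reading — with mean and sum available.  Secondary structure is consumed
as an annotation (CSV), never computed.

## Orientation

Per domain, the reference structure defines an origin (core centroid)
and two axes (first and second principal axes of the core coordinates;
signs point toward the highest-numbered core residue, making repeated
definitions bit-identical).  Each frame transports the reference axes by
the optimal least-squares (Kabsch) rotation of its core.  With C the
vector between domain origins: dC = |C|; AC1/AC2 = angles of the chain-a
axes to C; BC1/BC2 = angles of the chain-b axes to −C; AB = signed
dihedral between the planes (A1, C) and (C, B1), right-handed about C
pointing a→b, in (−180°, 180°].  The torsion uses circular statistics
(circular standard deviation); tilts and dC use linear ones.  The
variability summary flags the angle with the largest standard deviation
per window (angles compare in degrees; dC is excluded as a length).
This PCA + Kabsch-transport construction is a deterministic realisation
of reference-based interdomain orientation; its values are comparable
within this package, not numerically identical to any external tool's
anchor conventions.

## Markov state models

Features are inverse CA–CA distances of designated inter-chain residue
pairs (inverse distances emphasise short-range changes and saturate for
separated chains).  tICA solves C(τ)v = λC(0)v with mean-free data,
symmetrised C(τ), and a 10⁻⁸ ridge on C(0); zero-variance columns are
removed and reported.  Microstates come from seeded k-means (k-means++,
10 restarts).  Transition counts use the sliding window within each
trajectory; the model is restricted to the largest *strongly* connected
set of the directed count graph — an absorbing tail is excluded, and
strictly one-way data collapse to their recurrent part, which is the
textbook behaviour (batches containing both directions of the process,
as unbiased simulations of a reversible system produce, stay fully
connected).  The default estimator symmetrises counts, (C+Cᵀ)/2,
row-normalised — detailed balance then holds exactly with π proportional
to the symmetrised row sums; a non-reversible row-normalised estimator
is available by flag.  Implied timescales are t_i = −τ/ln λ_i.

PCCA+ is implemented as an inner-simplex vertex search on the dominant
eigenvector rows (successive farthest-point vertices, membership matrix
from the inverse vertex matrix, clipped and renormalised
row-stochastic).  Macrostate populations aggregate π over crisp
assignments; mean first-passage times solve the standard linear system
on the microstate chain and average source states by stationary weight.
The Chapman–Kolmogorov test compares membership-weighted macrostate
self-transition probabilities predicted by T(τ)^k against re-estimates
at lag kτ, with bootstrap bands over trajectories (blocks of one
trajectory when only one is given) plus a 0.02 absolute slack so that
ultra-regular data do not flag sub-percent deviations.

RMSD clustering aligns all frames on chain a, builds the full pairwise
RMSD matrix, cuts an average-linkage dendrogram at the distance cutoff
(default 0.1 Å), and reports each cluster's medoid as representative.

## Synthetic data: what it emulates, and what it does not

The **toy dimer** is a regular cylindrical lattice: an interface ring of
residues facing the partner chain across a mirror plane (five backbone
pseudo-atoms per residue, with a CB pseudo-atom carrying the designed
contact), and a 12-fold-symmetric rear block whose symmetry lets an
interdomain torsion leave the interface contacts and the SASA nearly
unchanged; one off-ring residue breaks the axial symmetry so the
per-domain principal axes are well-defined.  About a fifth of the
designed contacts sit marginally inside the 4.5 Å cutoff (4.44 Å) so
that Q fluctuates in a noisy bound ensemble, as it does in real
bound-state trajectories — several detectors rely on that fluctuation.

The **programmed dissociation** holds the bound pose (plus Gaussian
jitter, default 0.25 Å per coordinate), then at the encounter frame
breaks a designated subset of contacts (their CB slides along the
interface ring, staying equally buried), twists the rear block of chain
b by the torsion angle, and shifts chain b slightly along the separation
axis, with the persistent contacts holding their bound-pose geometry; at
the unbound frame chain b moves far enough that every inter-chain
distance exceeds twice the contact cutoff.  Default transitions sit at
50 % and 80 % of the frames.

The **Langevin simulator** integrates one CV with BAOAB (stable and
configurationally accurate at the default 0.002 ps step even at the well
curvatures of the benchmark potentials, where Euler–Maruyama already
distorts the variance), friction 1/ps, unit mass, T = 300 K, reflective
walls at the domain edges.  Hills (default 0.1 kJ/mol × 0.05 nm every
5000 steps) are deposited at the instantaneous CV; the bias and its
force live on the integration grid (2001 points) and are linearly
interpolated, so the per-step cost is independent of the hill count.
The analysis-side `bias_potential` evaluates the exact Gaussian sum.

None of this emulates explicit solvent, force fields, periodic boundary
conditions or multidimensional CVs.  Passing benchmarks therefore
establish the correctness of the *analysis* chain — descriptor algebra,
fitting, reweighting, estimators — under controlled ground truth, not
the physical fidelity of any particular simulation protocol.  Problem
sizes in the test suite and acceptance script (60–1000-frame
trajectories, 40–60-residue chains, 10⁶–5×10⁶-step Langevin runs,
3-run systems in the nine-system panel) are chosen as the smallest
scales at which each estimator's behaviour is clearly resolved.

## Known limitations

* The unbound detector (Q × SASA) needs a fluctuating bound ensemble;
  on noise-free synthetic input it collapses onto the dissociation
  detector.
* The LOO interval is a sensitivity range with low coverage by
  construction (see above).
* Depths from truncated, escape-limited runs underestimate the true
  well depth by O(k_BT): a run dissociates when bias plus a thermal
  fluctuation crosses the barrier.  Relative comparisons across systems
  (the depth–T_m correlation) are robust to this shared bias; absolute
  depths require converged, non-truncated sampling in a closed CV range.
* Well-tempered metadynamics, block-error analysis and Bayesian MSMs
  are out of scope.
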
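# Methods

This note documents the models and numerical choices behind `tieskit`:
what each stage computes, the defaults and why, what the synthetic-data
generator does and does not emulate, and known limitations.

## Hybrid dual-topology construction

### Structural MCS

The MCS is the maximum-cardinality *connected common induced subgraph* of
the two ligand graphs. Two atoms may pair iff their elements are
identical; bond order is ignored for matching (a configurable
`strict_bond_order` mode also requires equal orders) but preserved in the
output. Induced matching means bond presence must agree in both ligands
over every mapped pair, so the mapped substructures are genuinely the same
molecule fragment. Hydrogens are matched only once their bonded heavy atom
is matched — they never seed a mapping — and they count as ordinary atoms
in all region sizes.

The search is an exact branch-and-bound: each node of the search tree
either assigns the canonically smallest frontier atom of A to a compatible
atom of B or excludes it permanently, with a reachability bound for
pruning. MCS is NP-hard in general, so the search carries a state budget
(default 10⁶ states); past it, the best mapping found is extended greedily
and the result is flagged `exact=False`. Ligand-sized graphs (tens of
atoms) stay far below the budget in practice. Where two maximum mappings
exist the first in canonical search order is kept, so results are
deterministic; across pruning strategies, ties break on the
lexicographically smallest sorted pair list, then on canonical strategy
order.

### Charge-tolerance pruning

Defaults: `tol_atom = tol_net = 0.1` e, independently configurable (a
relaxation to 0.14 e is a documented use case for charged or highly
polarized alchemical regions). The net criterion is interpreted as
|Σ(q_A − q_B)| over retained pairs ≤ `tol_net`. Both criteria apply to
every atom, hydrogens included; whether hydrogen charges should instead be
folded into their heavy atom is ambiguous, so per-atom is the default and
the summed variant is left to the caller (prune on heavy-atom graphs).

One atom pair is removed per iteration. The candidate set is restricted to
removals that can make progress: pairs violating the per-atom criterion
while any exist, otherwise (net-only violation) pairs whose Δq shares the
sign of the net sum — removing any other pair cannot shrink |Σ Δq|, and a
candidate of the right sign always exists. Within the candidates, the
strategy orders by:

| strategy | priority |
|---|---|
| `max_diff` | largest \|Δq\| |
| `terminal_first` | terminal in current MCS, then largest \|Δq\| |
| `border_first` | adjacent to an unmapped atom in either parent, then largest \|Δq\| |
| `terminal_and_border` | border first, then terminal, then largest \|Δq\| |

(The combined strategy checks border membership before terminality; the
two sets usually overlap heavily and some fixed order is required.)
Ties break on smallest `(atom_id_A, atom_id_B)`. If a removal disconnects
the mapped substructure, the largest component is kept (ties to the one
holding the smallest atom id) and the rest moves to the alchemical
regions, recorded in the removal trace — this keeps the MCS single and
connected, which the anchoring scheme requires. Atoms whose only link to
the MCS was a removed atom (e.g. its hydrogens) leave automatically
through this rule.

### Regions and sizes

Disappearing = atoms of A outside the mapping; appearing = atoms of B
outside it. The merged bond list carries MCS bonds once (A-side ids) plus
each region's internal and anchoring bonds; anchors of bond order > 1 are
legal but warned about, since the scheme expects single-bond anchors.
`alchemical_size = n_dis + n_app` (regions above 40 atoms are flagged:
precision degrades with alchemical-region size), and
`transformation_size = |n_dis − n_app|` (above 10 is classed a large
transformation).

## λ protocol

Windows: 0, 0.05, 0.1, 0.2, …, 0.9, 0.95, 1 — endpoints, 0.05 shoulders,
interior spacing 0.1; 13 windows total. The scaling factors are the unique
linear interpolants of the breakpoints, clamped outside their ramps:

* vdW: disappearing 1 − λ, appearing λ;
* electrostatics: disappearing max(0, 1 − λ/0.55) — zero at and beyond
  0.55; appearing clamp((λ − 0.45)/0.55, 0, 1) — zero at and below 0.45.

The staggered electrostatic ramps avoid overlapping-charge singularities:
partial charges never act on atoms whose vdW cores are nearly decoupled.
The soft-core vdW radius-shifting coefficient (default 5) is recorded and
emitted in config fragments but never evaluated — soft-core energies
belong to the MD engine. The NAMD-style fragment emitted by
`emit_protocol_config(cfg, "namd_fragment")` is advisory text, not
bit-compatible with any engine version; the YAML format round-trips.

## Free-energy estimator

Per window, per replica: the sample mean of the ∂U/∂λ series (production
data are assumed equilibrated; `discard_fraction`, default 0, exists for
raw streams). Per window: a nonparametric bootstrap over the per-replica
means — `n_boot` (default 5000) resamples of `resample_size` (default: the
ensemble size) replicas with replacement; the window mean is the grand
mean of resample means and its standard error their population
(n-denominator) standard deviation. The bootstrap unit is the replica, not
the timestep, because inter-replica variability dominates the error
budget; a timestep-level mode exists behind a flag for exploration but is
not the estimator. A single-replica window yields se = 0 with a warning.

Integration is composite trapezoidal quadrature — the standard TI
estimator, exact for linear mean profiles — with the quadrature weights
also propagating the window standard errors under an
independence-across-windows assumption: σ² = Σ w_i² se_i². The quadrature
rule is pluggable in the sense that `integrate_profile` accepts any
(λ, mean, se) profile.

Seeding: every RNG stream derives from the master seed by stable SHA-256
hashing of (seed, transformation, leg, λ), so results are independent of
evaluation order and byte-identical across runs.

`replica_slice_estimate` mimics a one-off simulation by taking replica k
at every window; no bootstrap is possible and σ is reported as absent
rather than zero. `subsample_convergence` re-estimates on random
k-replica subsets per window to expose the σ-versus-ensemble-size trend.
`progressive_protocol` implements adaptive ensemble sizing: start at a
floor (default 5), escalate by `step` (default 5, cap 40) only those
transformations with σ above the threshold (default 0.5 kcal/mol). The
step and cap defaults are package choices; the cap matches the largest
ensemble sizes used in replica-distribution studies.

## Distribution diagnostics

Moment coefficients use the population-moment (biased) forms
g1 = m₃/m₂^{3/2} and g2 = m₄/m₂² − 3 by default, with the bias-corrected
G1/G2 available behind a flag and always included in the report — which
estimator variant applies to published numbers is generally unstated, so
both are carried. Computation delegates to `scipy.stats`; tests validate
against closed forms (exponential skewness 2, uniform excess kurtosis
−1.2, skew-normal(α=5) skewness ≈ 0.851). The optional
D'Agostino–Pearson omnibus normality test is labeled an extension — no
claim is made that it is part of the core protocol. The CLT check
contrasts a parent sample's skewness with that of its bootstrap resample
means; cumulant scaling predicts attenuation by ≈ 1/√k for resamples of
size k.

## Benchmark metrics

MUE = mean|pred − exp|, RMSE, and Pearson r, each with a pair-level
nonparametric bootstrap SE (default n_boot 10 000) — how benchmark-table
standard errors are obtained is rarely printed, so the bootstrap is an
explicit, documented assumption here. Zero experimental (or predicted)
variance makes r undefined; it is reported absent with a diagnostic
rather than raised. Binning on |ΔΔG_exp| uses edges [1, 2, 3] kcal/mol by
default; bins with fewer than two records report counts only. No
regression-dilution correction is applied: with noisy experimental values
the correction is itself unreliable, so raw correlations are reported.
Rank correlations are deliberately not computed by default (Pearson only);
nothing prevents a caller from applying `scipy.stats.spearmanr` to the
same table.

## Synthetic-data generator

The generator emulates the statistical structure of ensemble TI data, not
the physics:

* **Truth**: per-leg mean ∂U/∂λ profiles are polynomials in λ, so the true
  ΔG is an exact integral and the trapezoid of the truth is the best
  recoverable value.
* **Replica offsets**: each replica draws one offset from a configurable
  family — normal, skew-normal (α, default 5), Student-t (df > 2), or a
  two-component normal mixture — standardized to zero mean and unit
  variance before scaling, so the expected window mean always equals the
  profile. Default scale 5 kcal/mol: with tens of replicas this spreads
  window means over ~20 kcal/mol, the regime observed in real ensembles.
  Offsets are *persistent across windows* by default, modeling
  initial-condition divergence that shifts a replica's whole profile.
* **Within-replica noise**: iid Gaussian, default sd 2 kcal/mol; samples
  every 2 ps are treated as effectively independent. An AR(1) mode
  (`ar1_rho`) exists for autocorrelation studies.
* Defaults mirror the standard protocol: 13 windows, 5 replicas, 2000
  samples per replica (4 ns at 2 ps).

**Persistent offsets versus the estimator's error model.** With
persistent offsets, window errors within a leg are perfectly correlated,
while the estimator propagates them as independent — so σ understates the
true spread of ΔG by roughly √(Σw_i²) ≈ 0.3 under the standard schedule.
This is a real property of ensemble TI error propagation, not an artifact:
persistent replica-level bias is exactly what independence assumptions
miss. Parameter-recovery studies therefore use the generator's
`per_window_offsets=True` mode, which matches the estimator's assumption
and isolates the question "does the estimator recover the truth within its
stated uncertainty when its noise model holds". Under that mode, 3σ
coverage over 200 seeded transformations (normal and skew-normal families)
exceeds 95% in the test suite. Passing tests therefore validate the
estimator's internal consistency; they do not show that σ is calibrated
against replica-persistent bias in real MD data, where larger ensembles —
not tighter error propagation — are the remedy.

What the generator does **not** emulate: force-field energetics,
conformational kinetics, equilibration transients, window-to-window
correlation structure other than the persistent/per-window dichotomy, and
any dependence of noise on λ.

Test problem sizes are deliberately small (tens of samples per replica,
hundreds of bootstrap resamples) — chosen so the statistical assertions
have comfortable margins while the whole battery, including the
200-transformation recovery study and 50-pair exhaustive MCS
cross-check, runs in seconds to minutes on one CPU.

## File formats

Gradients: TSV with `#`-prefixed metadata headers under
`<transformation>/<leg>/lambda_<λ>/rep_<k>.tsv`; λ rendered
trailing-zero-free and matched numerically with tolerance 1e-9; replicas
numbered from 1, gapless. kcal/mol is canonical; kJ/mol converts on read
(÷4.184, logged). The NAMD-style importer is a regex dialect profile
(default: `TI:` lines, first float after the step number) — engine output
grammars vary by version, so it is explicitly best-effort and
configurable, not a fidelity claim.

Ligands: TRIPOS MOL2 is parsed directly (ATOM charge column 9; element
from the SYBYL type, falling back to the atom name for lowercase
force-field types such as GAFF's `ca`), because antechamber-typed MOL2
files are the dominant dialect in this workflow and fall outside rdkit's
Sybyl-only MOL2 support. SDF goes through rdkit, with charges in a named
property (default `PartialCharges`, one value per atom line).

All result files embed tool version, a configuration hash and the master
seed.

## Known limitations

* The MD engine, solvation, equilibration, REST2 enhanced sampling, and
  charge derivation (AM1-BCC/RESP) are out of scope; charges are consumed
  as given.
* Soft-core energies are never evaluated; the shift coefficient is
  metadata.
* The error model treats windows as independent (see above).
* The exact MCS search is exponential in the worst case; the budget line
  guards runtime, at the cost of a flagged heuristic result on
  pathological inputs.
* 3-D information is ignored in matching (no pose alignment, no chirality
  constraints); coordinates pass through to optional PDB output only.
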
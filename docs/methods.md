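# Methods

This note records the models behind each module, the defaults that
matter, and the choices made where the design was genuinely open. No
empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Fold templates

A fold is represented coarsely: ordered helix/strand elements (loops are
the gaps), a residue–residue contact map, per-residue burial classes and
a reference sequence. Numbering is 1-based inclusive everywhere.

* **Contacts** are computed between representative side-chain positions —
  Cβ, Cα for glycine — at a cutoff of 8.0 Å with a minimum sequence
  separation of 3, the standard coarse-grained convention. Both values
  are exposed as arguments.
* **Burial** is a pure function of contact count: core at ≥ 6 contacts,
  surface at ≤ 2, boundary between. These thresholds are heuristic and
  config-exposed; nothing downstream depends on their absolute values,
  only on the classes they induce, and the classification is tested
  against an independent recount of the contact list. No attempt is made
  to reproduce any published core-membership list, which typically
  reflects manual inspection.

## Threading and catastrophic interactions

Embeddings are **contiguous** (short position *i* → long position
*i* + offset, no gaps): loop-length remodelling of the host fold is
modelled by supplying a different long template, not by gapped
alignment. An alignment is admissible when the anchor elements overlap
by ≥ 4 residues (about one helical turn).

Conflict taxonomy (a declared stand-in for visual/all-atom clash
inspection; validated behaviourally, not numerically):

| kind | trigger | severity |
|---|---|---|
| `buried_polar` | D/E/K/R/N/Q/H at a core position of either fold | 2.0 |
| `helix_breaker` | P inside a helix, past the first turn (≥ 4 residues in) | 3.0 |
| `strand_breaker` | P anywhere in a strand | 3.0 |
| `overpacked_pair` | contacting core pair whose summed residue volume exceeds 1.25 × the reference pair's volume | 1.0 |
| `underpacked_core` | G/A at a core position whose own-plus-partner volume falls to ≤ ½ the reference budget | 0.5 |

Every position is scored in the long-fold context; window positions are
additionally scored in the short-fold context, so one conflict per
triggered context is recorded. Residue volumes are Zamyatnin-type mean
residue volumes (Å³). Severities are ordinal only: alignments are ranked
by **count first**, then total severity, then number of kind-matched
element correspondences, then offset, which makes the ranking robust to
the severity weights.

*Underpacking* deserves a note: the trigger compares the volume of the
residue plus its contact partners against the same sum over the
reference sequence, so a single G substitution in an otherwise native
core rarely fires it — it is meant to catch hollowed-out cores, not
single conservative shrinkages.

## Coarse energy

`E = w_c Σ_contacts P[s_i, s_j] + w_b Σ_i B[burial_i, s_i] +
w_s Σ_{i∈elements} S[kind_i, s_i]`, weights (1.0, 1.0, 0.5).

The tables are knowledge-based *in style* but derived from standard
scales rather than shipped as a literature matrix: the contact potential
is `P[a,b] = −(h_a + h_b)/4` on the Kyte–Doolittle scale (burying
hydrophobic pairs is favourable), burial terms are ±h transfer-style
vectors, and secondary-structure propensities are a three-level
former/neutral/breaker table with proline heavily penalised in both
element kinds. Only orderings are meaningful and only orderings are ever
asserted. An `ExternalScorer` protocol (`(sequence, template) → float`)
lets an all-atom scorer replace this energy wherever it is accepted; no
binding is shipped.

## Cluster resolution and stability optimisation

Conflict positions are grouped into connected components of the contact
graph restricted to conflict positions plus their contact partners;
components are split along the sequence to at most 6 positions and
singletons are padded with a sequence neighbour. Within a cluster the
search is exhaustive over per-position candidate alphabets (default
`AGSTVLIFYDEKRNQ` — no Cys, Pro, Trp, Met, His) with a lexicographic
objective: (1) zero conflicts attributed to the cluster, (2) fewest
mutations from the current sequence, (3) lowest combined dual energy
(long + embedded-window short), (4) alphabetical. Conservation
deliberately outranks energy. If nothing is feasible the
minimal-conflict assignment under the same chain is taken and a warning
logged.

Numerical choices: energies are compared after rounding to 10⁻⁶ so the
alphabetical tie-break, not floating-point noise, decides exact ties;
when the full candidate product exceeds 2000 assignments, per-position
candidate lists are pruned to the best single substitutions so the
product fits (the truly exhaustive regime is what the oracle tests
exercise).

Stability optimisation outside the window is a greedy per-position
sweep: accept the best substitution that strictly lowers the long-fold
energy and does not increase the total conflict count; repeat until a
sweep accepts nothing, up to 20 sweeps. The stopping rule is this
package's own convergence criterion for an otherwise unspecified
"repeat until done" step. The embedded window is never edited after
merging, at every stage — the short construct is always byte-identical
to the window (enforced and property-tested, including through
C-terminal tail grafts, which may only touch residues beyond the
window).

## Thermodynamics

Two-state Gibbs–Helmholtz throughout, R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹,
temperatures accepted in °C and converted to K internally, ΔG_folding
negative for stable folds. The three-state node is composed by linkage —
ΔG_switch = ΔG_short − ΔG_long from two separately measured constructs —
never fitted directly to one curve. Populations use a log-sum-exp form
so extreme stabilities cannot overflow; the naive Boltzmann form is the
test oracle.

Melt fitting: six parameters (T_m, ΔH_m, two linear baselines) with ΔC_p
fixed by policy — a user value or `per_residue:<n>` at 0.014
kcal mol⁻¹ K⁻¹ per residue, a common empirical estimate; the resolved
policy is recorded in the fit output. Baselines are initialised from the
grid ends, five T_m starts are spread across the grid, and the
lowest-SSE solution wins, making the fit deterministic per curve. A fit
is flagged degenerate when the T_m uncertainty exceeds the grid span or
the fitted transition amplitude is under 5× the residual RMS — flat
curves and biphasic melts are thereby rejected rather than silently
fitted; biphasic (three-state) melts are out of the model's scope by
design. The unfolded baseline can be borrowed from a destabilised
reference variant and held fixed.

## Function models

* Competitive inhibition with enzyme depletion ignored ([E] = 1 nM,
  K_I ≥ tens of nM); a tight-binding (Morrison) correction is a known
  limitation, and a warning is logged when inhibitor levels come within
  10× of the enzyme concentration. Substrate grid 0.1–10 µM, inhibitor
  0/50/100 nM by default. The two-stage estimate (per-level
  Michaelis–Menten fits, then inverse-variance-weighted regression of
  K_M(app) on [I], K_I = K_M(0)/slope) is the classical diagnostic; the
  global one-stage fit is the **primary estimator** — with only three
  inhibitor levels the two-stage slope is intrinsically noisy, and the
  recovery study in the acceptance script shows the global fit's median
  error is roughly half the two-stage one at 5 % rate noise. Both are
  reported.
* Retention: `elution_cv = 1 + [sites]/K_D` (frontal-affinity
  fast-equilibrium form — the operational rule "complete retention after
  20 CV on 100 µM sites" then corresponds to an order-of-magnitude bound
  of K_D ≤ 1 µM, which is exactly the bound text emitted). Whether the
  original retention calls involved more than this rule is unknowable
  from the assay description; only the rule is implemented.
* CSP: `√((w_H Δδ_H)² + (w_N Δδ_N)²)`, w_H = 1, w_N = 0.2.

## Synthetic data

`make_fold_pair` builds a βαββαβ long fold from an explicit idealized 3D
layout — strands as a flat pleated sheet (5 Å spacing), helices packed
6.5 Å above it (1.5 Å rise, 100°/residue, 2.3 Å radius), loops arced
away — and excises the short fold from the planted window, so contacts
and burial are geometrically coherent rather than random. Reference
sequences are drawn per burial class (hydrophobics at core, mixed
elsewhere); planted conflicts are lysines at long-core window positions;
decoy offsets are pushed to the conflict floor with *plant-neutral
mines* (prolines at double-loop positions, lysines at double-surface
positions) whose effect at every other offset is computed analytically
and then verified from scratch with the real scorer. Generation retries
up to 100 layouts and fails with a parameter hint. Everything is a pure
function of the spec and its seed.

Defaults mirror the study conditions the pipeline targets: a 90-residue
host with a 56-residue embedded fold at offset 10 (window 11–66,
matching the ~50 % size ratio of the real node pairs), a 16-residue
shared anchor helix, 3 planted conflicts against a decoy floor of 6.
What the generator does **not** emulate: real packing detail,
sequence-like composition, loop-length variation between fold families,
or any resemblance to natural S6/G_A/G_B sequences beyond topology — so
passing tests demonstrate the correctness of the algorithms, not that
the conflict taxonomy captures real structural chemistry.

With an 8 Å Cβ cutoff on an idealized compact layout the default burial
policy classifies most element residues as core; the generated toys are
therefore core-heavy compared with real proteins. This is harmless for
the planted-recovery guarantee but worth knowing when reading generated
templates.

Melt simulation uses the standard scan grid (20–100 °C in 0.5 °C steps)
with typical 222 nm baselines; kinetics simulation applies multiplicative
lognormal noise of a given coefficient of variation (mean-unbiased).

## Problem sizes

The recovery studies run 100 melt replicates at 2 % noise and 200
kinetics replicates at 5 % noise; planted-alignment recovery uses 50
generated pairs; oracle-equivalence tests enumerate clusters of ≤ 3
positions over a 6-letter alphabet. These sizes give stable medians
while keeping the full suite and the acceptance script fast on a single
CPU.

## Known limitations

* The conflict taxonomy and coarse energy are stand-ins for all-atom
  evaluation; they are validated by behaviour (oracle equivalence,
  planted recovery, monotonicity), not against experimental energetics.
* No gapped embeddings, backbone remodelling or structure prediction.
* Two-state melts only; chemical denaturation and unfolding kinetics are
  out of scope.
* Percent identity is positional over an embedding-defined alignment —
  there is no general pairwise aligner here, by design.
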
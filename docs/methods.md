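# Methods

This note documents the models and procedures implemented in `offtarget`,
the parameters that matter, what the synthetic study set does and does not
emulate, and the design decisions taken where the underlying methodology is
open to interpretation.

## Scope and assumptions

The toolkit is strictly 2D and ligand-centric: every prediction is a
function of the molecular graph and an annotated reference library. No
conformers, docking or binding-site information enter anywhere, and the
predictions are *binding* hypotheses only — functional direction (agonist
vs antagonist vs inhibitor) is outside the contract, which is why the
safety screen flags liability targets for functional follow-up instead of
rejecting them.

All potencies live on one scale, pActivity = −log₁₀(concentration in
mol/L) = 9 − log₁₀(value in nM), pooling IC50/Ki/EC50/Kd with the assay
type retained for filtering. Replicate measurements for the same
(compound, target, type) collapse to the most potent value — conservative
for confirmation calls, and logged.

## Molecular representation

**Pharmacophore typing** uses a versioned SMARTS rule table (`v1`) over the
six-label vocabulary {DON, ACC, ARO, HYD, POS, NEG}: donors are N/O/S
bearing hydrogen; acceptors are N/O with an available lone pair, excluding
amide nitrogens and nitro oxygens; ARO is aromatic perception; HYD is
non-aromatic carbon, divalent sulfur or halogen away from polar atoms;
POS/NEG approximate physiological-pH charge (formal charges plus aliphatic
amines and carboxylic acids). The table is deliberately explicit and
deterministic rather than exhaustive.

**Fingerprints** are hashed linear paths: all simple paths of 1..7 atoms,
labeled by element, aromaticity and formal charge plus bond orders, hashed
with blake2b into 2048 bits. Including single-atom paths makes even
one-heavy-atom molecules distinguishable; the stable hash makes bit sets
identical across processes and platforms. Tanimoto similarity of two empty
fingerprints is defined as 0 (with a warning) to avoid spurious perfect
matches between featureless fragments.

**FPD** counts, for each of the 21 unordered feature pairs, the topological
distance between every featured atom pair, in bins 1..10 plus an overflow
bin. **SHED** is the natural-log Shannon entropy of each pair's normalized
distance histogram (bounded by ln 11 under the default binning). **PHRAG**
records one feature-label string per featured atom pair, taken along its
shortest path (2..7 atoms); among equally short paths the lexicographically
smallest string in either direction is kept, which makes the profile
invariant to atom reindexing.

**Physchem**: molecular weight from standard atomic masses, Crippen atomic
contributions for logP, Ertl fragment sums for TPSA, SMARTS-based HBD/HBA,
amide and rotatable-bond counts, and an ESOL-style logS estimate (flagged
as an estimate; it is the one property not backed by a fragment table).
The 3/75 rule partitions profiles into compliant (logP < 3 and TPSA > 75
Å²), lipophilic (logP > 3 and TPSA < 75) and intermediate, with boundary
values (exactly 3 or exactly 75) assigned to intermediate so the partition
is total and unambiguous.

## The six methods

**SIM** scores a target as the maximum similarity between the query and the
target's ligands, per descriptor channel: PHRAG multiset Tanimoto
(Σ min / Σ max over fragment counts), FPD histogram intersection after
global normalization, and SHED similarity exp(−‖ΔH‖/s₀) with s₀ = 2.0 (a
scale chosen so that typical inter-family SHED distances of 2–4 map to
similarities well below the default floor of 0.2). Max-over-ligands rather
than mean implements nearest-neighbor logic. The pipeline-level SIM score
is the maximum over the three channels.

**SEA** compares the query(-associated set) against each target's full
ligand set (default membership cutoff pActivity ≥ 5.0, i.e. 10 µM,
configurable). The raw score RS sums Tanimoto values ≥ τ (default τ =
0.57, configurable and recalibratable per fingerprint). The null model is
fitted empirically: random compound-set pairs at several set-size products
n give μ(n) and σ(n) as linear (optionally power-law) fits, with R²
diagnostics stored and grid points clipped when the library is small. The
p-value uses the extreme-value form p = 1 − exp(−e^(−zπ/√6 − γ)) with γ
the Euler–Mascheroni constant; z = (RS − μ(n))/σ(n). On the synthetic
library this calibration yields near-uniform p-values for random pairs
(Kolmogorov–Smirnov statistic ≈ 0.08–0.10 at 500 pairs). For the consensus
the SEA method score is 1 − p.

**SAS** re-specifies "simplest active subgraph" as frequent
pharmacophore-typed subgraph signatures — the underlying production method
is unpublished, and this is the largest fidelity gap in the package. Per
target, all connected induced subgraphs of ≤ 8 atoms of every active are
enumerated (ESU), canonicalized *on the feature-label graph* (dummy atoms
carrying a label-set id as isotope, single bonds, canonical SMILES — so two
chemically different embeddings of the same labeled motif serialize
identically), and subgraphs present in ≥ 80% of actives become the
signature, smallest first, capped at 100. The prediction score is the
fraction of signature subgraphs embedded in the query (set membership of
canonical strings). Targets with fewer than 3 actives are skipped with a
warning.

**SAR** trains one L2-regularized logistic model per target on fingerprint
bits, positives = the ligand set, negatives sampled 3:1 (seeded) from
compounds not annotated to the target. The score is the logistic output;
an all-zero fingerprint scores exactly the squashed intercept.

**MLM** trains three classifiers per target — a 200-tree random forest, an
RBF SVM (C = 10) and a single-hidden-layer network (64 units) — on
identical flattened, normalized FPD matrices, with balanced class weights
to offset the 3:1 negative sampling. Targets need ≥ 10 positives. The
consensus is a majority vote (≥ 2 of 3, configurable to unanimity); the
method score is (positive votes)/3.

**XPI** is the ligand-set overlap index XPI(a,b) = |L_a ∩ L_b| /
min(|L_a|, |L_b|) (0 when either set is empty; 1 on the diagonal for
non-empty sets). Prediction propagates seed scores — the per-target best
score across the other five methods — through the index:
score(b) = max_a score(a)·XPI(a,b), floored at 0.05.

## Consensus

The pseudo-score is the weighted mean of the six method scores with equal
weights by default and absent methods contributing 0 at full weight,
clipped to [0, 1]. Two certainty rules force S = 1.00: the query is a
library member with the same annotated mechanism of action for the target,
or ≥ 5 of 6 methods each score ≥ 0.55 ("most methods agree",
operationalized; configurable). S ≥ 0.55 is significant. Aggregation is
monotone: raising any single method score never lowers S.

Confirmation is bookkeeping, not modeling: a prediction is confirmed iff
any activity record exists for the (drug, target) pair, and the best
measured pActivity is the maximum over records. Class summaries report the
confirmation percent as the *floored* integer — the only convention
consistent with the bundled per-class benchmark counts (e.g. 3080/3768 →
81, 1137/1788 → 63). Affinity bins use pActivity > 7 (< 100 nM), [8, 9)
(10–1 nM) and ≥ 9 (< 1 nM); the open/closed ends are this package's
documented choice.

## Expression refinement

Atlases are gene × tissue matrices in log2(TPM+1), one per species, with
ortholog maps (human symbol → species symbol, at most one per species). A
prediction is "expressed" for a tissue program iff its gene's maximum over
the requested tissues is ≥ θ (default 1.0 ≈ TPM 1). Genes absent from the
atlas are kept and flagged `no_data`: the expression criterion requires
presence evidence, and absence of data is not evidence of absence.
"Relatively high" expression, used only for report annotations, means at
or above the gene's own 75th cross-tissue percentile.

Heatmap clustering is agglomerative with average linkage on 1 − Pearson
correlation across tissues. Rows are sorted lexicographically by gene
symbol before clustering, which fixes tie-breaking and makes the leaf
order invariant to input row order; constant rows get the maximum distance
2.0 (logged). The clustered, row-z-scored matrix is always written as TSV
next to the image so downstream checks never read pixels.

## Exposure triage

pCmax = 6 − log₁₀(Cmax in µM), rounded to two decimals half-away-from-zero
(the convention that reproduces 13 of the 14 bundled panel values; the
Sirolimus row, 0.0160 µM printed as 7.7800 instead of 7.80, is
arithmetically irreconcilable and documented as such). Sub-micromolar
potency means pIC50 > 6.0 strictly; engagement means pIC50 ≥ pCmax. The
engagement direction follows the worked exposure table — sub-µM potency at
or above exposure implies meaningful target engagement — because the
accompanying prose states the comparison in the pharmacologically inverted
direction; the package follows the table and records the conflict here.
Similarly, the triage keeps off-targets with pIC50 *above* 6 (the table
header's convention) where the prose says "below".

The verdict is a total, mutually exclusive partition: *pursue* (evidence ∧
expression ∧ S > 0.55 ∧ sub-µM), *optimize_potency* (criteria hold, weak
or unmeasured potency), *deprioritize* (any criterion fails), always with
a rationale string.

## Synthetic study set

The generator emulates, at desk scale, the statistical shape of a large
annotated reference universe. Defaults: 8 targets, one scaffold family
each (ring cores decorated at two positions from a 16-substituent
vocabulary; 136 unique decorations per core, so validity and uniqueness
hold by construction), 20 actives per target, potencies normal in
pActivity (mean 7.0, sd 0.7), 10% of compounds annotated to a second
target to plant cross-pharmacology, and held-out analog queries (new
decorations, never in the library; 3 per target by default). An in-vitro
confirmation table measures each query–true-target link with probability
0.63. The atlas plants one home tissue per target gene at log2(TPM+1) ≈
5.0 over |N(0.5, 0.2)| background, per species, with identity-with-suffix
orthologs. Everything is a pure function of (spec, seed), byte-identical
across runs; the recovery study is calibrated at seed 17.

What the generator does **not** emulate: medicinal-chemistry diversity
(activity cliffs, scaffold hops, stereochemistry), assay noise and
inter-assay disagreement, class-imbalanced target panels, or correlated
tissue programs. Passing recovery tests therefore demonstrates that the
pipeline's machinery is wired correctly and discriminates planted families
— not that it reaches production accuracy on real pharmacology. Headline
counts from production-scale screens (tens of thousands of interactions)
are inputs for arithmetic checks, not quantities this package can
regenerate.

## Numerical choices and degenerate inputs

* Rounding: pCmax half-away-from-zero to 2 dp; class percentages floored.
* SEA σ(n) has a floor of 10⁻³; an unreachable τ (> 1) degenerates to
  RS = 0 everywhere with μ = 0, σ = floor.
* The extreme-value p saturates at 1.0 in double precision for z ≲ −4;
  strict monotonicity holds on the representable range.
* Empty molecules yield empty fingerprints (not an error); molecules with
  < 2 featured atoms yield all-zero FPD/SHED and empty PHRAG.
* Disconnected atom pairs carry the sentinel distance −1 and are excluded
  from FPD/PHRAG.
* All randomness (negative sampling, background fitting, generator draws)
  flows from a single integer seed per run; sklearn seeds are derived from
  it, and every CLI output carries the seed and a config hash in its
  header. Problem sizes in the shipped tests and acceptance study (160
  library compounds, 24 queries, 500 calibration pairs, 20 clustering
  seeds) were chosen as the smallest sets at which the stochastic
  properties are stable.

## Known limitations

* SAS signatures are induced subgraphs of the feature graph; non-induced
  embeddings are not matched, and very promiscuous label patterns (pure
  ARO chains) transfer between aromatic scaffolds, making SAS the least
  discriminative method — by design it trades precision for recall.
* SEA's background fit is linear in the set-size product; heavy-tailed
  libraries may prefer the power-law form (available via configuration).
* The MLM vote is discrete (0, ⅓, ⅔, 1), so rankings among targets tie
  frequently; the consensus, not MLM alone, is the intended ranking.
* Ortholog mapping is 1:1 by symbol; paralog expansion is out of scope.
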
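# offtarget

Consensus 2D off-target prediction and exposure-aware drug-repurposing
triage for small molecules.

A drug rarely binds only its intended protein: typical small molecules
engage on the order of 6–11 targets. Those unintended interactions are both
a safety liability and a repurposing opportunity. `offtarget` is a toolkit
for computational and nonclinical scientists who want to (1) predict which
proteins a compound is likely to bind using only its 2D structure and an
annotated reference library, (2) keep only predictions whose target is
actually expressed in the tissues of interest, and (3) decide — against the
drug's clinical exposure — whether a predicted off-target is worth pursuing.

## The method

Six orthogonal ligand-centric methods each score a query molecule against
every target in an annotated reference library (compounds, targets and
potencies normalized to pActivity = −log₁₀ M):

| method | idea |
|---|---|
| **SIM** | nearest-neighbor similarity in three pharmacophore descriptor channels: PHRAG fragment strings (multiset Tanimoto), feature-pair distance distributions FPD (histogram intersection), and their Shannon-entropy summaries SHED (distance kernel) |
| **SEA**  | set-wise similarity of the query against a target's full ligand set: raw score RS = Σ Tc over pairs with Tc ≥ τ, standardized by a fitted random background μ(n), σ(n), with the extreme-value tail p = 1 − exp(−e^(−zπ/√6 − γ)) |
| **SAS**  | frequent pharmacophore-typed subgraph signatures shared by a target's actives; score = fraction of signatures embedded in the query |
| **SAR**  | per-target regularized logistic models on hashed linear-path fingerprint bits |
| **MLM**  | majority vote of three classifiers (random forest, SVM, single-hidden-layer network) trained on flattened FPD descriptors |
| **XPI**  | cross-pharmacology propagation through ligand-set overlap, XPI(a,b) = \|L_a ∩ L_b\| / min(\|L_a\|, \|L_b\|) |

The per-method scores are aggregated into a **pseudo-score** S ∈ [0, 1]
(equal-weight mean by default). S ≥ 0.55 is significant; S = 1.00 is
reserved for the certainty rule (the query is a training-set member with
the same mechanism of action, or ≥ 5 of 6 methods agree at the threshold).

Predictions are then refined by tissue expression (gene × tissue atlases in
log2(TPM+1), per species, with ortholog mapping) and triaged against
clinical exposure: pCmax = −log₁₀(Cmax in M) is compared with the measured
pIC50, where pIC50 > 6.0 means sub-micromolar potency and pIC50 ≥ pCmax
means the free plasma concentration can engage the target. A prediction is
*pursued* when literature evidence, tissue expression, pseudo-score > 0.55
and sub-µM potency all hold; criteria met with weak potency routes to
*potency optimization*; anything else is *deprioritized*.

Because the reference universes behind production off-target screens are
proprietary, the package ships a synthetic fixture generator
(`offtarget.synthetic`): scaffold families with planted target annotations,
log-normal potencies, cross-pharmacology overlaps and tissue-specific
expression blocks, all byte-reproducible under a seed.

## Worked example

Physicochemical profile and the logP/TPSA "3/75" risk category:

```python
from offtarget import chem, compute_physchem, classify_rule_3_75

mol = chem.parse_smiles("CC(C)Cc1ccc(cc1)C(C)C(=O)O", mol_id="ibuprofen")
p = compute_physchem(mol)
print(f"MW {p.mw:.2f}  logP {p.logp:.2f}  TPSA {p.tpsa:.2f}")
print(classify_rule_3_75(p))
```

```
MW 206.28  logP 3.07  TPSA 37.30
lipophilic
```

`lipophilic` means logP > 3 with TPSA < 75 Å² — the higher-risk corner of
the 3/75 rule. Exposure arithmetic works the same way:
`compute_pcmax(0.052)` → `7.28`, and a measured pIC50 of 7.5 against that
exposure gives `exposure_flags(7.5, 7.28)` → sub-µM, engaged, margin +0.22.

The full pipeline from the shell:

```bash
offtarget simulate --seed 17 --out fix
offtarget predict fix/queries.tsv --library fix/activities.csv \
    --confirmations fix/confirmations.csv --seed 17 --out pred
offtarget triage --predictions pred/predictions.tsv \
    --atlas fix/atlas_human.tsv --exposure fix/exposure.csv \
    --evidence fix/evidence.csv --seed 17 --out tri
```

`pred/predictions.tsv` holds one row per drug–target pair with the six
method scores and the consensus:

```
drug_id   target_id  ... score_mlm  score_xpi  pseudo_score  significant  status
Q_T01_01  T01        ... 0.0        1.0        1.0           True         predicted_unconfirmed
Q_T01_01  T02        ... 1.0        1.0        0.725032      True         predicted_unconfirmed
```

and `tri/triage.tsv` adds expression, exposure and the verdict per pair
(`pursue` / `optimize_potency` / `deprioritize`, with a rationale string).
Liability targets (5-HT2B, PPARγ, hERG, cKIT) are flagged `safety_review`;
the toolkit predicts binding only, never functional direction, so these are
routed to follow-up rather than auto-rejected.

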
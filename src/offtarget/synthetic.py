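"""Synthetic fixture generator: a desk-scale reference library with planted truth.

The real reference universe behind large off-target screens (millions of
annotated compounds) is proprietary; this module emulates its statistical
shape at desk scale. Each target owns a scaffold family — a ring core
decorated at two positions from a fixed substituent vocabulary — so chemical
validity is guaranteed by construction and family membership is the planted
ground truth. Potencies are log-normal in concentration (normal in
pActivity, mean 7.0, sd 0.7); a configurable fraction of compounds is
annotated to a second target to plant cross-pharmacology for XPI. The
companion expression atlas plants one high-expression home tissue per target
gene over a low noisy background, per species, with identity-with-suffix
ortholog maps.

Everything is a pure function of (spec, seed): same spec, byte-identical
outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import library as libmod
from .library import ReferenceLibrary, from_frames
from .transcriptomics import ExpressionAtlas

#: Scaffold cores (two decoration points each); one per target, in order.
SCAFFOLD_TEMPLATES = (
    "c1cc({A})cc({B})c1",       # benzene
    "c1cc({A})nc({B})c1",       # pyridine
    "C1CC({A})CC({B})C1",       # cyclohexane
    "c1c({A})sc({B})c1",        # thiophene
    "c1c({A})oc({B})c1",        # furan
    "C1CC({A})NC({B})C1",       # piperidine
    "c1nc({A})cc({B})n1",       # pyrimidine
    "C1CC({A})C({B})C1",        # cyclopentane
    "c1cc({A})c({B})[nH]1",     # pyrrole
    "C1CC({A})OC({B})C1",       # tetrahydropyran
)

#: Decoration vocabulary (16 substituents → 136 unordered pairs per core).
SUBSTITUENTS = ("C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "CO", "CN",
                "CCO", "Cl", "F", "C(=O)O", "C(=O)N", "C#N")

DEFAULT_TISSUES = ("brain", "liver", "kidney", "heart", "lung",
                   "muscle", "blood", "skin")

DEFAULT_SPECIES = ("human", "mouse", "rat", "dog", "monkey")


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 17
    n_targets: int = 8
    actives_per_target: int = 20
    overlap_fraction: float = 0.1        # compounds annotated to a 2nd target
    potency_mean: float = 7.0            # pActivity scale
    potency_sd: float = 0.7
    # expression atlas
    n_background_genes: int = 12
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    species: tuple[str, ...] = DEFAULT_SPECIES
    block_mean: float = 5.0              # planted home-tissue expression
    background_mean: float = 0.5
    noise_sd: float = 0.2
    #: fraction of query–target links that receive an in-vitro measurement
    confirmation_rate: float = 0.63

    def __post_init__(self):
        if self.n_targets < 1 or self.actives_per_target < 1:
            raise SyntheticError("counts must be >= 1")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise SyntheticError("overlap fraction must be in [0,1]")
        if self.n_targets > len(SCAFFOLD_TEMPLATES):
            raise SyntheticError(
                f"at most {len(SCAFFOLD_TEMPLATES)} targets supported "
                "(one scaffold each)")

    def target_id(self, i: int) -> str:
        return f"T{i + 1:02d}"


def _decorations() -> list[tuple[str, str]]:
    """All unordered substituent pairs, fixed order (136 per core)."""
    return list(itertools.combinations_with_replacement(SUBSTITUENTS, 2))


def _shuffled_decorations(spec: SyntheticSpec, target_index: int
                          ) -> list[tuple[str, str]]:
    """Deterministic per-target permutation of the decoration list."""
    rng = np.random.default_rng([spec.seed, 1001, target_index])
    decs = _decorations()
    return [decs[i] for i in rng.permutation(len(decs))]


def _n_queries(spec: SyntheticSpec, held_out_fraction: float) -> int:
    return max(1, math.ceil(held_out_fraction * spec.actives_per_target))


_CLASS_CYCLE = libmod.TARGET_CLASSES


def gen_reference_library(spec: SyntheticSpec
                          ) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Generate the annotated library and its ground-truth table.

    Compounds are decorated cores; each target's actives come from its own
    scaffold; ``overlap_fraction`` of compounds get a second annotation to
    the cyclically next target (planting cross-pharmacology).
    """
    needed = spec.actives_per_target
    if needed > len(_decorations()):
        raise SyntheticError("decoration vocabulary too small for requested count")
    rng = np.random.default_rng([spec.seed, 2002])

    comp_rows, act_rows, truth_rows = [], [], []
    targ_rows = []
    for t in range(spec.n_targets):
        tid = spec.target_id(t)
        targ_rows.append({
            "target_id": tid, "gene_symbol": tid,
            "target_class": _CLASS_CYCLE[t % len(_CLASS_CYCLE)],
            "species": "human"})
        template = SCAFFOLD_TEMPLATES[t]
        decs = _shuffled_decorations(spec, t)[:needed]
        for k, (a, b) in enumerate(decs):
            cid = f"{tid}_C{k + 1:03d}"
            smiles = template.format(A=a, B=b)
            comp_rows.append({"compound_id": cid, "smiles": smiles,
                              "canonical_smiles": smiles, "name": cid})
            pact = float(rng.normal(spec.potency_mean, spec.potency_sd))
            pact = min(max(pact, 4.0), 11.0)
            act_rows.append({
                "compound_id": cid, "target_id": tid, "activity_type": "IC50",
                "value_nm": libmod.pactivity_to_nm(pact), "pactivity": pact,
                "moa": "inhibitor", "source": "synthetic"})
            truth_rows.append({"compound_id": cid, "scaffold_index": t,
                               "true_targets": tid})

    # cross-pharmacology: a fixed fraction annotated to the next target
    n_overlap = int(round(spec.overlap_fraction * len(comp_rows)))
    if n_overlap and spec.n_targets > 1:
        pick = rng.choice(len(comp_rows), size=n_overlap, replace=False)
        for idx in sorted(pick):
            row = truth_rows[idx]
            t = row["scaffold_index"]
            second = spec.target_id((t + 1) % spec.n_targets)
            pact = float(rng.normal(spec.potency_mean, spec.potency_sd))
            pact = min(max(pact, 4.0), 11.0)
            act_rows.append({
                "compound_id": row["compound_id"], "target_id": second,
                "activity_type": "IC50",
                "value_nm": libmod.pactivity_to_nm(pact), "pactivity": pact,
                "moa": "inhibitor", "source": "synthetic-overlap"})
            row["true_targets"] = row["true_targets"] + ";" + second

    lib = from_frames(pd.DataFrame(comp_rows), pd.DataFrame(targ_rows),
                      pd.DataFrame(act_rows))
    truth = pd.DataFrame(truth_rows)[["compound_id", "true_targets",
                                      "scaffold_index"]]
    return lib, truth


def gen_query_drugs(spec: SyntheticSpec, lib: ReferenceLibrary,
                    held_out_fraction: float = 0.15) -> pd.DataFrame:
    """Held-out analog queries: fresh decorations of the library scaffolds.

    Returns a frame (query_id, smiles, true_targets) disjoint from the
    library compound table by construction.
    """
    if not (0.0 < held_out_fraction <= 1.0):
        raise SyntheticError("held_out_fraction must be in (0, 1]")
    n_q = _n_queries(spec, held_out_fraction)
    needed = spec.actives_per_target + n_q
    if needed > len(_decorations()):
        raise SyntheticError("decoration vocabulary too small for queries")
    rows = []
    for t in range(spec.n_targets):
        tid = spec.target_id(t)
        template = SCAFFOLD_TEMPLATES[t]
        decs = _shuffled_decorations(spec, t)
        for k, (a, b) in enumerate(decs[spec.actives_per_target:needed]):
            rows.append({"query_id": f"Q_{tid}_{k + 1:02d}",
                         "smiles": template.format(A=a, B=b),
                         "true_targets": tid})
    return pd.DataFrame(rows)


def gen_expression_atlas(spec: SyntheticSpec
                         ) -> tuple[dict[str, ExpressionAtlas], pd.DataFrame]:
    """Per-species atlases with one planted home tissue per target gene.

    Background cells are |N(background_mean, noise_sd)| clipped at 0; each
    target gene's home tissue (assigned cyclically) gets block_mean plus the
    same noise. Ortholog maps are identity-with-species-suffix.
    """
    target_genes = [spec.target_id(t) for t in range(spec.n_targets)]
    bg_genes = [f"BG{i + 1:02d}" for i in range(spec.n_background_genes)]
    genes = target_genes + bg_genes
    tissues = list(spec.tissues)
    home = {g: tissues[i % len(tissues)] for i, g in enumerate(target_genes)}

    atlases: dict[str, ExpressionAtlas] = {}
    ortho_rows = []
    for s_idx, sp in enumerate(spec.species):
        rng = np.random.default_rng([spec.seed, 3003, s_idx])
        suffix = "" if sp == "human" else f"_{sp}"
        values = np.abs(rng.normal(spec.background_mean, spec.noise_sd,
                                   size=(len(genes), len(tissues))))
        for i, g in enumerate(target_genes):
            j = tissues.index(home[g])
            values[i, j] = max(spec.block_mean + rng.normal(0.0, spec.noise_sd), 0.0)
        mat = pd.DataFrame(np.round(values, 4),
                           index=[g + suffix for g in genes], columns=tissues)
        mat.index.name = "gene"
        atlases[sp] = ExpressionAtlas(species=sp, matrix=mat,
                                      provenance=f"synthetic seed={spec.seed}")
        for g in genes:
            ortho_rows.append({"human_symbol": g, "species": sp,
                               "species_symbol": g + suffix})
    return atlases, pd.DataFrame(ortho_rows)


def gen_confirmations(spec: SyntheticSpec, queries: pd.DataFrame) -> pd.DataFrame:
    """In-vitro assay results for a fraction of query–target links.

    Emulates the post-prediction confirmation step: each (query, true target)
    pair is measured with probability ``confirmation_rate``, with potencies
    from the same log-normal model as the library.
    """
    rng = np.random.default_rng([spec.seed, 5005])
    rows = []
    for row in queries.sort_values("query_id").itertuples(index=False):
        for tid in row.true_targets.split(";"):
            if rng.random() >= spec.confirmation_rate:
                continue
            pact = float(rng.normal(spec.potency_mean, spec.potency_sd))
            pact = min(max(pact, 4.0), 11.0)
            rows.append({"compound_id": row.query_id, "target_id": tid,
                         "activity_type": "IC50",
                         "value_nm": f"{libmod.pactivity_to_nm(pact):.6g}",
                         "moa": "inhibitor", "source": "synthetic-assay"})
    return pd.DataFrame(rows, columns=["compound_id", "target_id",
                                       "activity_type", "value_nm", "moa",
                                       "source"])


def gen_exposure_table(spec: SyntheticSpec, drugs: pd.DataFrame) -> pd.DataFrame:
    """Exposure records (Cmax log-uniform in 0.01..10 µM) for a drug table
    with columns (drug id in the first column, true_targets)."""
    rng = np.random.default_rng([spec.seed, 4004])
    id_col = drugs.columns[0]
    rows = []
    for row in drugs.sort_values(id_col).itertuples(index=False):
        cmax = float(10 ** rng.uniform(-2, 1))
        rows.append({"drug_id": getattr(row, id_col),
                     "cmax_um": round(cmax, 4),
                     "intended_targets": row.true_targets,
                     "dose_note": "synthetic"})
    return pd.DataFrame(rows)


def write_fixture_dir(spec: SyntheticSpec, outdir,
                      held_out_fraction: float = 0.15) -> dict[str, Path]:
    """Emit every file format the pipeline consumes; byte-stable under seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib, truth = gen_reference_library(spec)
    queries = gen_query_drugs(spec, lib, held_out_fraction)
    atlases, orthologs = gen_expression_atlas(spec)
    # the held-out queries are the drugs under triage
    exposure = gen_exposure_table(spec, queries)

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, sep: str = "\t",
               index: bool = False) -> None:
        p = outdir / name
        df.to_csv(p, sep=sep, index=index)
        paths[name] = p

    comp = lib.compounds.sort_values("compound_id")
    smi_path = outdir / "compounds.smi"
    smi_path.write_text("".join(f"{r.smiles}\t{r.compound_id}\n"
                                for r in comp.itertuples(index=False)))
    paths["compounds.smi"] = smi_path

    act = lib.activities.sort_values(
        ["compound_id", "target_id", "activity_type"]).copy()
    tclass = dict(zip(lib.targets["target_id"], lib.targets["target_class"]))
    smiles_of = dict(zip(lib.compounds["compound_id"], lib.compounds["smiles"]))
    act_out = pd.DataFrame({
        "compound_id": act["compound_id"],
        "smiles": act["compound_id"].map(smiles_of),
        "target_id": act["target_id"],
        "target_class": act["target_id"].map(tclass),
        "activity_type": act["activity_type"],
        "value_nm": act["value_nm"].map(lambda v: f"{v:.6g}"),
        "moa": act["moa"], "source": act["source"]})
    _write("activities.csv", act_out, sep=",")

    _write("ground_truth.tsv", truth.sort_values("compound_id"))
    _write("queries.tsv", queries.sort_values("query_id"))
    for sp, atlas in sorted(atlases.items()):
        _write(f"atlas_{sp}.tsv", atlas.matrix, index=True)
    _write("orthologs.tsv",
           orthologs.sort_values(["human_symbol", "species"]))
    _write("exposure.csv", exposure.sort_values("drug_id"), sep=",")
    _write("confirmations.csv", gen_confirmations(spec, queries), sep=",")

    evidence = pd.DataFrame([
        {"target_id": spec.target_id(t), "disease": "synthetic_indication",
         "source": "planted"} for t in range(spec.n_targets)])
    _write("evidence.csv", evidence, sep=",")
    return paths
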
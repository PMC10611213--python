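"""The six 2D ligand-centric target-prediction methods.

Each method scores a query molecule against every target in the reference
library and emits per-target scores in [0, 1]:

* SIM — nearest-neighbor similarity in three descriptor channels
  (PHRAG multiset Tanimoto, FPD histogram intersection, SHED distance kernel).
* SEA — set-wise ligand similarity: raw score = sum of above-threshold
  Tanimoto values against the target's ligand set, standardized against a
  fitted random background and converted to an extreme-value p-value.
* SAS — frequent pharmacophore-typed subgraph signatures per target; the
  score is the fraction of signature subgraphs embedded in the query.
* SAR — per-target regularized logistic models on fingerprint bits.
* MLM — majority vote of three classifiers (random forest, SVM, single
  hidden-layer neural network) trained on flattened FPD descriptors.
* XPI — cross-pharmacology propagation through ligand-set overlap indices.

All randomness flows from one integer seed; given (library, seed, config)
every method is deterministic.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from . import chem
from .chem import BitFingerprint, FeatureAssignment, Molecule, tanimoto
from .library import DEFAULT_LIGAND_CUTOFF, ReferenceLibrary

log = logging.getLogger("offtarget.predict")

METHODS = ("SAS", "SAR", "SIM", "SEA", "MLM", "XPI")

EULER_GAMMA = float(np.euler_gamma)


class PredictError(ValueError):
    pass


@dataclass(frozen=True)
class MethodScore:
    method: str
    target_id: str
    score: float
    evidence: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise PredictError(f"method score out of [0,1]: {self.score}")


# ---------------------------------------------------------------------------
# SIM — descriptor similarities

def phrag_similarity(a: chem.PHRAGProfile, b: chem.PHRAGProfile) -> float:
    """Multiset Tanimoto: Σ min(c_a, c_b) / Σ max(c_a, c_b)."""
    ca, cb = dict(a.fragments), dict(b.fragments)
    keys = set(ca) | set(cb)
    if not keys:
        return 0.0
    mins = sum(min(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    maxs = sum(max(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    return mins / maxs if maxs else 0.0


def fpd_similarity(a: chem.FPDMatrix, b: chem.FPDMatrix) -> float:
    """Histogram intersection of the globally normalized FPD matrices."""
    fa, fb = a.flatten(), b.flatten()
    sa, sb = fa.sum(), fb.sum()
    if sa == 0 or sb == 0:
        return 1.0 if sa == sb else 0.0
    return float(np.minimum(fa / sa, fb / sb).sum())


#: Scale of the SHED distance kernel exp(−d / s0).
SHED_KERNEL_SCALE = 2.0


def shed_similarity(a: chem.SHEDVector, b: chem.SHEDVector,
                    scale: float = SHED_KERNEL_SCALE) -> float:
    d = float(np.linalg.norm(a.entropies - b.entropies))
    return math.exp(-d / scale)


_SIM_FUNCS = {"PHRAG": phrag_similarity, "FPD": fpd_similarity,
              "SHED": shed_similarity}


def predict_sim(query: Molecule, lib: ReferenceLibrary, descriptor: str,
                cutoff: float = DEFAULT_LIGAND_CUTOFF,
                floor: float = 0.2) -> list[MethodScore]:
    """Per target: max similarity between the query and the target's ligands
    in one descriptor channel; targets scoring below ``floor`` are omitted."""
    if descriptor not in _SIM_FUNCS:
        raise PredictError(f"unknown SIM descriptor {descriptor!r}")
    if not lib.descriptors:
        raise PredictError("descriptor cache not built; build it first")
    simf = _SIM_FUNCS[descriptor]
    kind = descriptor.lower()
    feats = chem.assign_features(query)
    q_fpd = chem.compute_fpd(query, feats)
    q_desc = {"phrag": chem.compute_phrag(query, feats),
              "fpd": q_fpd, "shed": chem.compute_shed(q_fpd)}[kind]
    out = []
    for tid in sorted(lib.target_ids()):
        best, best_cid = 0.0, None
        for cid in lib.ligand_set(tid, cutoff):
            s = simf(q_desc, lib.descriptor(cid, kind))
            if s > best:
                best, best_cid = s, cid
        if best >= floor and best_cid is not None:
            out.append(MethodScore("SIM", tid, min(best, 1.0),
                                   {"descriptor": descriptor,
                                    "nearest": best_cid, "similarity": best}))
    return out


# ---------------------------------------------------------------------------
# SEA — set-wise similarity statistic

@dataclass(frozen=True)
class SEAResult:
    raw_score: float
    n: int                       # set-size product
    mu: float
    sigma: float
    z: float
    p: float


@dataclass
class SEABackground:
    """Fitted null model for the SEA raw score as a function of the set-size
    product n: μ(n) and σ(n) are linear (or power-law) fits over random
    compound-set pairs."""

    tau: float
    mu_coeffs: tuple[float, float]       # (intercept, slope) or (log a, b)
    sigma_coeffs: tuple[float, float]
    form: str = "linear"                 # or "power"
    r2_mu: float = float("nan")
    r2_sigma: float = float("nan")
    reps: int = 0
    seed: int = 0
    sigma_floor: float = 1e-3

    def mu(self, n: float) -> float:
        a, b = self.mu_coeffs
        return a + b * n if self.form == "linear" else math.exp(a) * n ** b

    def sigma(self, n: float) -> float:
        a, b = self.sigma_coeffs
        s = a + b * n if self.form == "linear" else math.exp(a) * n ** b
        return max(s, self.sigma_floor)


def sea_pvalue(z: float) -> float:
    """Extreme-value tail p = 1 − exp(−e^(−zπ/√6 − γ)); strictly decreasing in z."""
    x = -z * math.pi / math.sqrt(6.0) - EULER_GAMMA
    # for large x, 1 - exp(-e^x) -> 1; for very negative x, ≈ e^x
    if x > 700:
        return 1.0
    return float(-math.expm1(-math.exp(x)))


def raw_sea_score(query_fps: list[BitFingerprint],
                  ligand_fps: list[BitFingerprint], tau: float) -> float:
    """RS = Σ Tc over cross-set pairs with Tc ≥ τ (plain double loop)."""
    rs = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-fingerprint pairs contribute 0
        for fq in query_fps:
            for fl in ligand_fps:
                t = tanimoto(fq, fl)
                if t >= tau:
                    rs += t
    return rs


def fit_sea_background(lib: ReferenceLibrary, tau: float = 0.57,
                       n_grid: tuple[int, ...] = (4, 16, 64, 144, 256),
                       reps: int = 40, seed: int = 0,
                       form: str = "linear") -> SEABackground:
    """Fit μ(n), σ(n) from raw scores of random compound-set pairs.

    For each grid value n (a set-size product), ``reps`` random pairs of
    compound sets of size √n are drawn from the library and scored.
    """
    if reps < 30:
        raise PredictError("need at least 30 replicates per grid point")
    if len(n_grid) < 2:
        raise PredictError("degenerate background grid")
    if not lib.descriptors:
        raise PredictError("descriptor cache not built; build it first")
    rng = np.random.default_rng(seed)
    cids = sorted(lib.compound_ids())
    fps = {cid: lib.descriptor(cid, "fingerprint") for cid in cids}
    # drop grid points that need more compounds than the library holds
    feasible = [n for n in n_grid
                if 2 * max(1, int(round(math.sqrt(n)))) <= len(cids)]
    if len(feasible) < 2:
        raise PredictError("library too small for the background grid")
    if len(feasible) < len(n_grid):
        log.warning("SEA background grid clipped to %s (library has %d compounds)",
                    feasible, len(cids))
    ns, mus, sigmas = [], [], []
    for n in feasible:
        k = max(1, int(round(math.sqrt(n))))
        scores = []
        for _ in range(reps):
            pick = rng.choice(len(cids), size=2 * k, replace=False)
            set_a = [fps[cids[i]] for i in pick[:k]]
            set_b = [fps[cids[i]] for i in pick[k:]]
            scores.append(raw_sea_score(set_a, set_b, tau))
        ns.append(k * k)
        mus.append(float(np.mean(scores)))
        sigmas.append(float(np.std(scores, ddof=1)))

    ns_arr = np.asarray(ns, dtype=float)
    def _fit(y):
        y = np.asarray(y, dtype=float)
        if form == "linear":
            x = ns_arr
        else:
            keep = y > 0
            if keep.sum() < 2:
                return (0.0, 0.0), 0.0
            x, y = np.log(ns_arr[keep]), np.log(y[keep])
        b, a = np.polyfit(x, y, 1)
        pred = a + b * x
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return (float(a), float(b)), r2

    mu_c, r2_mu = _fit(mus)
    sg_c, r2_sg = _fit(sigmas)
    return SEABackground(tau=tau, mu_coeffs=mu_c, sigma_coeffs=sg_c, form=form,
                         r2_mu=r2_mu, r2_sigma=r2_sg, reps=reps, seed=seed)


def predict_sea(query: Molecule, lib: ReferenceLibrary,
                background: SEABackground, tau: float | None = None,
                cutoff: float = DEFAULT_LIGAND_CUTOFF,
                query_set: list[Molecule] | None = None
                ) -> list[tuple[str, SEAResult]]:
    """Score the query(-associated set) against every target's ligand set;
    results sorted by p ascending (ties by target id)."""
    if background is None:
        raise PredictError("SEA background not fitted")
    tau = background.tau if tau is None else tau
    qset = query_set if query_set is not None else [query]
    q_fps = [chem.compute_fingerprint(m) for m in qset]
    out = []
    for tid in sorted(lib.target_ids()):
        ligands = lib.ligand_set(tid, cutoff)
        if not ligands:
            continue
        l_fps = [lib.descriptor(cid, "fingerprint") for cid in ligands]
        rs = raw_sea_score(q_fps, l_fps, tau)
        n = len(qset) * len(ligands)
        mu, sigma = background.mu(n), background.sigma(n)
        if sigma <= 0:
            raise PredictError(f"non-positive background sigma at n={n}")
        z = (rs - mu) / sigma
        out.append((tid, SEAResult(raw_score=rs, n=n, mu=mu, sigma=sigma,
                                   z=z, p=sea_pvalue(z))))
    out.sort(key=lambda item: (item[1].p, item[0]))
    return out


# ---------------------------------------------------------------------------
# SAS — frequent pharmacophore-typed subgraph signatures

# stable label-set -> isotope id over the 64 subsets of the vocabulary
_LABEL_IDS = {
    "+".join(combo): i + 1
    for i, combo in enumerate(
        itertools.chain.from_iterable(
            itertools.combinations(chem.FEATURE_VOCABULARY, r)
            for r in range(len(chem.FEATURE_VOCABULARY) + 1)))
}


def _connected_subgraphs(adj: list[list[int]], max_atoms: int) -> set[frozenset[int]]:
    """All connected induced vertex sets of size ≤ max_atoms (ESU enumeration)."""
    results: set[frozenset[int]] = set()

    def extend(sub: frozenset[int], ext: set[int], root: int) -> None:
        results.add(sub)
        if len(sub) >= max_atoms:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {u for u in adj[w] if u > root and u not in sub}
            new_ext.discard(w)
            extend(sub | {w}, new_ext, root)

    n = len(adj)
    for v in range(n):
        extend(frozenset([v]), {u for u in adj[v] if u > v}, v)
    return results


def _feature_graph_string(mol: Molecule, features: FeatureAssignment,
                          atoms: frozenset[int]) -> str:
    """Canonical serialization of the pharmacophore-labeled subgraph: dummy
    atoms carrying the label-set id as isotope, single bonds, canonical
    SMILES of that label graph (independent of the underlying chemistry)."""
    index = {a: k for k, a in enumerate(sorted(atoms))}
    rw = RWMol()
    for a in sorted(atoms):
        atom = Chem.Atom(0)
        labs = features.labels[a]
        atom.SetIsotope(_LABEL_IDS["+".join(sorted(labs))])
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for b in mol.rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in atoms and j in atoms:
            rw.AddBond(index[i], index[j], Chem.BondType.SINGLE)
    m = rw.GetMol()
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return Chem.MolToSmiles(m, canonical=True)


def subgraph_signature_set(mol: Molecule, features: FeatureAssignment,
                           max_atoms: int = 8) -> set[str]:
    """Canonical strings of every connected pharmacophore-typed subgraph of
    the molecule with ≤ max_atoms atoms."""
    adj = [[nb.GetIdx() for nb in a.GetNeighbors()] for a in mol.rdmol.GetAtoms()]
    return {_feature_graph_string(mol, features, sub)
            for sub in _connected_subgraphs(adj, max_atoms)}


@dataclass(frozen=True)
class SubgraphSignature:
    target_id: str
    subgraphs: tuple[tuple[int, str], ...]   # (atom count, canonical string), smallest first
    fraction: float
    max_atoms: int
    n_actives: int

    def strings(self) -> set[str]:
        return {s for _, s in self.subgraphs}


@dataclass
class SASModel:
    signatures: dict[str, SubgraphSignature]
    fraction: float
    max_atoms: int
    #: per-molecule subgraph string cache keyed by canonical SMILES
    cache: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def query_strings(self, query: Molecule) -> set[str]:
        if query.smiles not in self.cache:
            feats = chem.assign_features(query)
            self.cache[query.smiles] = subgraph_signature_set(
                query, feats, self.max_atoms)
        return self.cache[query.smiles]


def build_sas_signatures(lib: ReferenceLibrary, fraction: float = 0.8,
                         max_atoms: int = 8,
                         cutoff: float = DEFAULT_LIGAND_CUTOFF,
                         max_signatures: int = 100) -> SASModel:
    """Per target: connected pharmacophore subgraphs (≤ max_atoms atoms)
    present in ≥ ``fraction`` of the target's actives, smallest first.
    Targets with fewer than 3 actives are skipped with a warning."""
    model = SASModel(signatures={}, fraction=fraction, max_atoms=max_atoms)
    sizes: dict[str, int] = {}
    for tid in sorted(lib.target_ids()):
        actives = lib.ligand_set(tid, cutoff)
        if len(actives) < 3:
            log.warning("SAS: target %s has %d actives (<3), skipped", tid, len(actives))
            continue
        doc_freq: dict[str, int] = {}
        for cid in actives:
            strings = model.query_strings(lib.molecule(cid))
            for s in strings:
                doc_freq[s] = doc_freq.get(s, 0) + 1
        need = math.ceil(fraction * len(actives))
        frequent = [s for s, c in doc_freq.items() if c >= need]
        for s in frequent:
            if s not in sizes:
                sizes[s] = Chem.MolFromSmiles(s, sanitize=False).GetNumAtoms()
        ranked = sorted(((sizes[s], s) for s in frequent))[:max_signatures]
        model.signatures[tid] = SubgraphSignature(
            target_id=tid, subgraphs=tuple(ranked), fraction=fraction,
            max_atoms=max_atoms, n_actives=len(actives))
    return model


def predict_sas(query: Molecule, model: SASModel) -> list[MethodScore]:
    """Score = fraction of each target's signature subgraphs embedded in the query."""
    q_strings = model.query_strings(query)
    out = []
    for tid in sorted(model.signatures):
        sig = model.signatures[tid]
        if not sig.subgraphs:
            continue
        hits = sum(1 for _, s in sig.subgraphs if s in q_strings)
        score = hits / len(sig.subgraphs)
        if score > 0:
            out.append(MethodScore("SAS", tid, score,
                                   {"n_signatures": len(sig.subgraphs), "hits": hits}))
    return out


# ---------------------------------------------------------------------------
# SAR — per-target regularized linear models on fingerprint bits

@dataclass
class SARModel:
    models: dict[str, object]            # target -> fitted LogisticRegression
    families: dict[str, str]             # target -> target class (family)
    bits: int
    seed: int


def _fp_array(fp: BitFingerprint) -> np.ndarray:
    x = np.zeros(fp.size, dtype=float)
    x[sorted(fp.bits)] = 1.0
    return x


def _sample_negatives(rng: np.random.Generator, pool: list[str],
                      n: int) -> list[str]:
    if not pool:
        return []
    idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [pool[i] for i in sorted(idx)]


def train_sar(lib: ReferenceLibrary, seed: int = 0,
              cutoff: float = DEFAULT_LIGAND_CUTOFF,
              neg_ratio: int = 3, min_positives: int = 3) -> SARModel:
    """One L2-regularized logistic scorer per target over fingerprint bits.

    Negatives are drawn (seeded) from compounds not annotated to the target,
    preferring the same target family to sharpen within-family separation."""
    from sklearn.linear_model import LogisticRegression

    if not lib.descriptors:
        raise PredictError("descriptor cache not built; build it first")
    rng = np.random.default_rng(seed)
    families = dict(zip(lib.targets["target_id"], lib.targets["target_class"]))
    fps = {cid: _fp_array(lib.descriptor(cid, "fingerprint"))
           for cid in sorted(lib.compound_ids())}
    models: dict[str, object] = {}
    for tid in sorted(lib.target_ids()):
        pos = lib.ligand_set(tid, cutoff)
        if len(pos) < min_positives:
            log.warning("SAR: target %s has %d actives, skipped", tid, len(pos))
            continue
        pool = sorted(set(fps) - set(pos))
        neg = _sample_negatives(rng, pool, neg_ratio * len(pos))
        if not neg:
            continue
        X = np.vstack([fps[c] for c in pos + neg])
        y = np.array([1] * len(pos) + [0] * len(neg))
        clf = LogisticRegression(C=1.0, max_iter=1000, random_state=int(seed) % (2**31))
        clf.fit(X, y)
        models[tid] = clf
    return SARModel(models=models, families=families,
                    bits=next(iter(fps.values())).size, seed=seed)


def predict_sar(query: Molecule, model: SARModel,
                floor: float = 0.0) -> list[MethodScore]:
    """Logistic-squashed model output per target (closed form on the bits)."""
    x = _fp_array(chem.compute_fingerprint(query, bits=model.bits))[None, :]
    out = []
    for tid in sorted(model.models):
        score = float(model.models[tid].predict_proba(x)[0, 1])
        if score >= floor:
            out.append(MethodScore("SAR", tid, min(max(score, 0.0), 1.0),
                                   {"family": model.families.get(tid, "")}))
    return out


# ---------------------------------------------------------------------------
# MLM — three-classifier consensus on FPD descriptors

@dataclass
class TargetClassifierBundle:
    target_id: str
    rf: object
    svm: object
    ann: object
    seed: int
    n_positives: int
    n_negatives: int
    descriptor_version: str = "fpd-v1"


def _fpd_vector(fpd: chem.FPDMatrix) -> np.ndarray:
    v = fpd.flatten()
    total = v.sum()
    return v / total if total > 0 else v


def train_mlm(lib: ReferenceLibrary, seed: int = 0,
              cutoff: float = DEFAULT_LIGAND_CUTOFF,
              min_positives: int = 10,
              neg_ratio: int = 3) -> dict[str, TargetClassifierBundle]:
    """Train RF / SVM / single-hidden-layer network per target on identical
    flattened-FPD matrices; targets with < min_positives actives are skipped."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if not lib.descriptors:
        raise PredictError("descriptor cache not built; build it first")
    rng = np.random.default_rng(seed)
    vecs = {cid: _fpd_vector(lib.descriptor(cid, "fpd"))
            for cid in sorted(lib.compound_ids())}
    bundles: dict[str, TargetClassifierBundle] = {}
    for tid in sorted(lib.target_ids()):
        pos = lib.ligand_set(tid, cutoff)
        if len(pos) < min_positives:
            log.warning("MLM: target %s has %d actives (<%d), skipped",
                        tid, len(pos), min_positives)
            continue
        pool = sorted(set(vecs) - set(pos))
        neg = _sample_negatives(rng, pool, neg_ratio * len(pos))
        X = np.vstack([vecs[c] for c in pos + neg])
        y = np.array([1] * len(pos) + [0] * len(neg))
        sk_seed = int(seed) % (2**31)
        # balanced class weights: negatives outnumber positives neg_ratio:1
        rf = RandomForestClassifier(n_estimators=200, random_state=sk_seed,
                                    class_weight="balanced")
        svm = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=sk_seed,
                  class_weight="balanced")
        ann = MLPClassifier(hidden_layer_sizes=(64,), max_iter=1500,
                            random_state=sk_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            rf.fit(X, y); svm.fit(X, y); ann.fit(X, y)
        bundles[tid] = TargetClassifierBundle(
            target_id=tid, rf=rf, svm=svm, ann=ann, seed=seed,
            n_positives=len(pos), n_negatives=len(neg))
    return bundles


def mlm_votes(query: Molecule, bundle: TargetClassifierBundle) -> tuple[int, int, int]:
    feats = chem.assign_features(query)
    x = _fpd_vector(chem.compute_fpd(query, feats))[None, :]
    return (int(bundle.rf.predict(x)[0]), int(bundle.svm.predict(x)[0]),
            int(bundle.ann.predict(x)[0]))


def consensus_from_votes(votes: tuple[int, int, int],
                         majority: int = 2) -> tuple[bool, float]:
    """(consensus positive?, score = positive votes / 3); majority default 2/3."""
    n_pos = sum(votes)
    return n_pos >= majority, n_pos / 3.0


def predict_mlm(query: Molecule, bundles: dict[str, TargetClassifierBundle],
                majority: int = 2) -> list[MethodScore]:
    out = []
    for tid in sorted(bundles):
        votes = mlm_votes(query, bundles[tid])
        positive, score = consensus_from_votes(votes, majority)
        if score > 0:
            out.append(MethodScore("MLM", tid, score,
                                   {"votes": list(votes), "consensus": positive}))
    return out


# ---------------------------------------------------------------------------
# XPI — cross-pharmacology index

def compute_xpi(lib: ReferenceLibrary,
                cutoff: float = DEFAULT_LIGAND_CUTOFF
                ) -> tuple[list[str], np.ndarray]:
    """XPI(a,b) = |L_a ∩ L_b| / min(|L_a|, |L_b|); 0 where a set is empty."""
    tids = sorted(lib.target_ids())
    sets = {tid: set(lib.ligand_set(tid, cutoff)) for tid in tids}
    n = len(tids)
    xpi = np.zeros((n, n))
    for i, a in enumerate(tids):
        for j, b in enumerate(tids):
            if i > j:
                continue
            la, lb = sets[a], sets[b]
            if not la or not lb:
                val = 0.0
            else:
                val = len(la & lb) / min(len(la), len(lb))
            xpi[i, j] = xpi[j, i] = val
    return tids, xpi


def predict_xpi(seed_scores: list[MethodScore], tids: list[str],
                xpi: np.ndarray, floor: float = 0.05) -> list[MethodScore]:
    """Propagate seed-target scores through the overlap index:
    score(b) = max over seeds a of score(a) · XPI(a, b), floored."""
    index = {tid: i for i, tid in enumerate(tids)}
    best: dict[str, tuple[float, str]] = {}
    for ms in seed_scores:
        if ms.target_id not in index:
            continue
        i = index[ms.target_id]
        for j, tid_b in enumerate(tids):
            val = ms.score * float(xpi[i, j])
            if val > best.get(tid_b, (0.0, ""))[0]:
                best[tid_b] = (val, ms.target_id)
    return [MethodScore("XPI", tid, min(val, 1.0), {"seed_target": seed})
            for tid, (val, seed) in sorted(best.items()) if val >= floor]


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class PredictorConfig:
    tau: float = 0.57                    # SEA Tanimoto threshold
    ligand_cutoff: float = DEFAULT_LIGAND_CUTOFF
    sim_floor: float = 0.2
    sas_fraction: float = 0.8
    sas_max_atoms: int = 8
    xpi_floor: float = 0.05
    sea_reps: int = 40
    mlm_min_positives: int = 10
    neg_ratio: int = 3
    mlm_majority: int = 2


class TargetPredictor:
    """Fits all six methods on a library and scores query molecules.

    The per-method pipeline scores are: SIM = max over the three descriptor
    channels; SEA = 1 − p; SAS/SAR/MLM/XPI as defined by their operations.
    """

    def __init__(self, lib: ReferenceLibrary, seed: int = 0,
                 config: PredictorConfig | None = None):
        self.lib = lib
        self.seed = seed
        self.config = config or PredictorConfig()
        self._fitted = False

    def fit(self) -> "TargetPredictor":
        cfg = self.config
        if not self.lib.descriptors:
            self.lib.build_descriptor_cache()
        self.sea_background = fit_sea_background(
            self.lib, tau=cfg.tau, reps=cfg.sea_reps, seed=self.seed)
        self.sas_model = build_sas_signatures(
            self.lib, fraction=cfg.sas_fraction, max_atoms=cfg.sas_max_atoms,
            cutoff=cfg.ligand_cutoff)
        self.sar_model = train_sar(self.lib, seed=self.seed,
                                   cutoff=cfg.ligand_cutoff,
                                   neg_ratio=cfg.neg_ratio)
        self.mlm_bundles = train_mlm(self.lib, seed=self.seed,
                                     cutoff=cfg.ligand_cutoff,
                                     min_positives=cfg.mlm_min_positives,
                                     neg_ratio=cfg.neg_ratio)
        self.xpi_targets, self.xpi_matrix = compute_xpi(self.lib, cfg.ligand_cutoff)
        self._fitted = True
        return self

    def predict_methods(self, query: Molecule) -> dict[str, dict[str, MethodScore]]:
        """All six methods' scores for one query: method → target → score."""
        if not self._fitted:
            raise PredictError("predictor not fitted; call fit() first")
        cfg = self.config
        out: dict[str, dict[str, MethodScore]] = {}

        sim_best: dict[str, MethodScore] = {}
        for desc in ("PHRAG", "FPD", "SHED"):
            for ms in predict_sim(query, self.lib, desc,
                                  cutoff=cfg.ligand_cutoff, floor=cfg.sim_floor):
                if ms.target_id not in sim_best or ms.score > sim_best[ms.target_id].score:
                    sim_best[ms.target_id] = ms
        out["SIM"] = sim_best

        sea = predict_sea(query, self.lib, self.sea_background,
                          cutoff=cfg.ligand_cutoff)
        out["SEA"] = {
            tid: MethodScore("SEA", tid, min(max(1.0 - res.p, 0.0), 1.0),
                             {"raw_score": res.raw_score, "z": res.z, "p": res.p})
            for tid, res in sea if res.raw_score > 0}

        out["SAS"] = {ms.target_id: ms for ms in predict_sas(query, self.sas_model)}
        out["SAR"] = {ms.target_id: ms
                      for ms in predict_sar(query, self.sar_model, floor=0.0)}
        out["MLM"] = {ms.target_id: ms
                      for ms in predict_mlm(query, self.mlm_bundles,
                                            majority=cfg.mlm_majority)}

        # XPI seeds: per-target best score across the other five methods
        seed_best: dict[str, float] = {}
        for method in ("SIM", "SEA", "SAS", "SAR", "MLM"):
            for tid, ms in out[method].items():
                seed_best[tid] = max(seed_best.get(tid, 0.0), ms.score)
        seeds = [MethodScore("XPI", tid, sc, {}) for tid, sc in sorted(seed_best.items())]
        out["XPI"] = {ms.target_id: ms
                      for ms in predict_xpi(seeds, self.xpi_targets,
                                            self.xpi_matrix, floor=cfg.xpi_floor)}
        return out

    def method_score_table(self, query: Molecule, query_id: str):
        """Long-format rows: query_id, method, target_id, score, evidence."""
        import json as _json

        import pandas as pd
        rows = []
        scores = self.predict_methods(query)
        for method in METHODS:
            for tid, ms in sorted(scores.get(method, {}).items()):
                rows.append({"query_id": query_id, "method": method,
                             "target_id": tid, "score": round(ms.score, 6),
                             "evidence_json": _json.dumps(ms.evidence, sort_keys=True,
                                                          default=float)})
        return pd.DataFrame(rows)
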
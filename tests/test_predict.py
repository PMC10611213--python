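"""Unit tests for the six prediction methods."""

import math

import numpy as np
import pytest

from offtarget import chem, library, predict, synthetic
from offtarget.chem import BitFingerprint, tanimoto
from offtarget.predict import (
    EULER_GAMMA,
    MethodScore,
    PredictError,
    build_sas_signatures,
    compute_xpi,
    consensus_from_votes,
    fit_sea_background,
    phrag_similarity,
    predict_sas,
    predict_sea,
    predict_sim,
    predict_xpi,
    raw_sea_score,
    sea_pvalue,
    subgraph_signature_set,
    train_sar,
)


def _toy_library():
    """2 targets, disjoint chemistry: phenols (T1) vs aliphatic amines (T2)."""
    import pandas as pd

    rows = []
    t1 = ["Oc1ccccc1", "Oc1ccccc1C", "Oc1ccccc1CC", "Oc1ccc(C)cc1",
          "Oc1ccc(CC)cc1", "Oc1cccc(C)c1"]
    t2 = ["NCCC", "NCCCC", "NCCCCC", "NCC(C)C", "NCCC(C)C", "NCCCCCC"]
    for i, smi in enumerate(t1):
        rows.append(("P%d" % i, smi, "T1", "Enzyme", "IC50", 50.0, "inhibitor", "toy"))
    for i, smi in enumerate(t2):
        rows.append(("A%d" % i, smi, "T2", "GPCR", "IC50", 50.0, "agonist", "toy"))
    df = pd.DataFrame(rows, columns=library.ACTIVITY_COLUMNS)
    comp = df[["compound_id", "smiles"]].drop_duplicates()
    comp = comp.assign(canonical_smiles=[chem.parse_smiles(s).smiles
                                         for s in comp["smiles"]],
                       name=comp["compound_id"])
    targ = df[["target_id", "target_class"]].drop_duplicates()
    targ = targ.assign(gene_symbol=targ["target_id"], species="human")
    acts = df[["compound_id", "target_id", "activity_type", "value_nm",
               "moa", "source"]]
    lib = library.from_frames(comp, targ, acts)
    lib.build_descriptor_cache()
    return lib


@pytest.fixture(scope="module")
def toy_lib():
    return _toy_library()


# ---------------------------------------------------------------------------
# score type

def test_method_score_range_enforced():
    with pytest.raises(PredictError):
        MethodScore("SIM", "T1", 1.2)


# ---------------------------------------------------------------------------
# SIM

class TestSIM:
    def test_self_similarity_one(self, toy_lib):
        query = toy_lib.molecule("P0")
        for desc in ("PHRAG", "FPD", "SHED"):
            scores = {s.target_id: s.score
                      for s in predict_sim(query, toy_lib, desc)}
            assert scores["T1"] == pytest.approx(1.0)

    def test_featureless_query_empty(self, toy_lib):
        # cyclopropane: only HYD features, shares no PHRAG fragments with
        # any phenol/amine ligand above the floor
        query = chem.parse_smiles("C1CC1")
        scores = predict_sim(query, toy_lib, "PHRAG", floor=0.5)
        assert all(s.score < 1.0 for s in scores)

    def test_analog_prefers_its_family(self, toy_lib):
        query = chem.parse_smiles("Oc1ccc(CCC)cc1")   # unseen phenol analog
        for desc in ("PHRAG", "FPD"):
            scores = {s.target_id: s.score
                      for s in predict_sim(query, toy_lib, desc, floor=0.0)}
            assert scores["T1"] > scores.get("T2", 0.0)

    def test_requires_descriptor_cache(self):
        lib = _toy_library()
        lib.descriptors = {}
        with pytest.raises(PredictError, match="cache"):
            predict_sim(chem.parse_smiles("CCO"), lib, "PHRAG")

    def test_phrag_multiset_tanimoto(self):
        a = chem.PHRAGProfile(fragments=(("x", 2), ("y", 1)))
        b = chem.PHRAGProfile(fragments=(("x", 1), ("z", 1)))
        # min-sum = 1, max-sum = 2 + 1 + 1 = 4
        assert phrag_similarity(a, b) == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# SEA

class TestSEA:
    def _fp(self, bits):
        return BitFingerprint(bits=frozenset(bits), size=64)

    def test_no_pair_reaches_tau(self):
        assert raw_sea_score([self._fp({1})], [self._fp({2})], 0.5) == 0.0

    def test_single_qualifying_pair(self):
        a, b = self._fp({1, 2, 3, 4, 5}), self._fp({1, 2, 3, 4, 6})
        tc = tanimoto(a, b)
        assert tc == pytest.approx(4 / 6)
        assert raw_sea_score([a], [b], 0.5) == pytest.approx(tc)

    def test_pvalue_closed_form_at_zero(self):
        assert sea_pvalue(0.0) == pytest.approx(
            1 - math.exp(-math.exp(-EULER_GAMMA)), abs=1e-12)
        assert sea_pvalue(0.0) == pytest.approx(0.4296, abs=1e-4)

    def test_pvalue_strictly_decreasing(self):
        # strictly decreasing over the float-representable range; the far
        # left tail saturates at 1.0 in double precision
        zs = np.linspace(-3, 10, 50)
        ps = [sea_pvalue(z) for z in zs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(0 <= p <= 1 for p in ps)
        assert sea_pvalue(-50.0) == 1.0

    def test_background_deterministic_under_seed(self, toy_lib):
        kw = dict(tau=0.57, n_grid=(4, 9, 16), reps=30)
        bg1 = fit_sea_background(toy_lib, seed=5, **kw)
        bg2 = fit_sea_background(toy_lib, seed=5, **kw)
        assert bg1.mu_coeffs == bg2.mu_coeffs
        assert bg1.sigma_coeffs == bg2.sigma_coeffs

    def test_unreachable_tau_gives_zero_scores(self, toy_lib):
        bg = fit_sea_background(toy_lib, tau=1.01, n_grid=(4, 9, 16), reps=30)
        assert bg.mu(9) == pytest.approx(0.0, abs=1e-12)
        assert bg.sigma(9) == bg.sigma_floor
        results = predict_sea(toy_lib.molecule("P0"), toy_lib, bg)
        assert all(r.raw_score == 0.0 for _, r in results)

    def test_mu_non_decreasing_in_n(self, toy_lib):
        bg = fit_sea_background(toy_lib, tau=0.3, n_grid=(4, 9, 16, 25), reps=30)
        assert bg.mu_coeffs[1] >= 0  # fitted slope

    def test_rs_matches_brute_force(self, toy_lib):
        """The reported raw score equals an independent double loop over the
        query × ligand-set Tanimoto values."""
        bg = fit_sea_background(toy_lib, tau=0.3, n_grid=(4, 9, 16), reps=30)
        query = chem.parse_smiles("Oc1ccc(CCC)cc1")
        results = dict(predict_sea(query, toy_lib, bg, cutoff=5.0))
        qfp = chem.compute_fingerprint(query)
        for tid in toy_lib.target_ids():
            expected = 0.0
            for cid in toy_lib.ligand_set(tid, 5.0):
                lfp = toy_lib.descriptor(cid, "fingerprint")
                inter = len(qfp.bits & lfp.bits)
                union = len(qfp.bits | lfp.bits)
                tc = inter / union if union else 0.0
                if tc >= 0.3:
                    expected += tc
            assert results[tid].raw_score == pytest.approx(expected)

    def test_results_sorted_by_p(self, toy_lib):
        bg = fit_sea_background(toy_lib, tau=0.3, n_grid=(4, 9, 16), reps=30)
        results = predict_sea(toy_lib.molecule("P0"), toy_lib, bg)
        ps = [r.p for _, r in results]
        assert ps == sorted(ps)


# ---------------------------------------------------------------------------
# SAS

class TestSAS:
    def test_planted_motif_recovered(self, toy_lib):
        """All phenol actives share the hydroxyl-on-ring motif; the signature
        set must contain subgraphs found in a fresh phenol analog."""
        model = build_sas_signatures(toy_lib, fraction=0.8, max_atoms=6)
        sig = model.signatures["T1"]
        assert sig.subgraphs
        analog = chem.parse_smiles("Oc1ccc(CCCC)cc1")
        analog_strings = subgraph_signature_set(
            analog, chem.assign_features(analog), max_atoms=6)
        assert sig.strings() <= analog_strings  # full recovery in the analog

    def _model_from_strings(self, strings):
        from offtarget.predict import SASModel, SubgraphSignature
        sig = SubgraphSignature(target_id="T", fraction=0.8, max_atoms=6,
                                n_actives=3,
                                subgraphs=tuple((1, s) for s in sorted(strings)))
        return SASModel(signatures={"T": sig}, fraction=0.8, max_atoms=6)

    def test_query_containing_every_signature_scores_one(self):
        query = chem.parse_smiles("Oc1ccccc1C")
        q_strings = subgraph_signature_set(query, chem.assign_features(query), 6)
        model = self._model_from_strings(sorted(q_strings)[:5])
        (score,) = predict_sas(query, model)
        assert score.score == 1.0

    def test_query_containing_no_signature_scores_zero(self):
        other = chem.parse_smiles("NCCCN")
        o_strings = subgraph_signature_set(other, chem.assign_features(other), 6)
        query = chem.parse_smiles("c1ccccc1")
        q_strings = subgraph_signature_set(query, chem.assign_features(query), 6)
        foreign = sorted(o_strings - q_strings)[:5]
        assert foreign
        model = self._model_from_strings(foreign)
        assert predict_sas(query, model) == []

    def test_small_targets_skipped(self, toy_lib, caplog):
        import logging

        import pandas as pd
        extra = toy_lib.activities.head(2).assign(target_id="T3")
        lib2 = library.ReferenceLibrary(
            compounds=toy_lib.compounds,
            targets=pd.concat([toy_lib.targets, pd.DataFrame([{
                "target_id": "T3", "gene_symbol": "T3",
                "target_class": "Kinase", "species": "human"}])],
                ignore_index=True),
            activities=pd.concat([toy_lib.activities, extra], ignore_index=True),
            descriptors=toy_lib.descriptors, molecules=toy_lib.molecules)
        with caplog.at_level(logging.WARNING):
            model = build_sas_signatures(lib2, fraction=0.8, max_atoms=5)
        assert "T3" not in model.signatures
        assert any("T3" in r.message for r in caplog.records)

    def test_signature_strings_invariant_to_atom_order(self):
        m1 = chem.parse_smiles("Oc1ccccc1C")
        from rdkit import Chem as RDChem
        m2 = chem.parse_smiles(
            RDChem.MolToSmiles(m1.rdmol, canonical=False, doRandom=True))
        s1 = subgraph_signature_set(m1, chem.assign_features(m1), 6)
        s2 = subgraph_signature_set(m2, chem.assign_features(m2), 6)
        assert s1 == s2


# ---------------------------------------------------------------------------
# SAR

class TestSAR:
    def test_training_compound_scores_high(self, toy_lib):
        model = train_sar(toy_lib, seed=3)
        scores = {s.target_id: s.score
                  for s in predict.predict_sar(toy_lib.molecule("P0"), model)}
        assert scores["T1"] > 0.5

    def test_cross_family_below_within_family(self, toy_lib):
        model = train_sar(toy_lib, seed=3)
        within, cross = [], []
        for cid in toy_lib.compound_ids():
            scores = {s.target_id: s.score
                      for s in predict.predict_sar(toy_lib.molecule(cid), model)}
            true = "T1" if cid.startswith("P") else "T2"
            other = "T2" if true == "T1" else "T1"
            within.append(scores[true])
            cross.append(scores[other])
        assert np.mean(within) > np.mean(cross)

    def test_zero_fingerprint_gives_squashed_intercept(self, toy_lib):
        model = train_sar(toy_lib, seed=3)
        clf = model.models["T1"]
        x = np.zeros((1, model.bits))
        expected = 1 / (1 + math.exp(-clf.intercept_[0]))
        assert clf.predict_proba(x)[0, 1] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# MLM

class TestMLMVotes:
    @pytest.mark.parametrize("votes,positive,score", [
        ((1, 1, 0), True, 2 / 3),
        ((1, 0, 0), False, 1 / 3),
        ((1, 1, 1), True, 1.0),
        ((0, 0, 0), False, 0.0),
    ])
    def test_majority_rule(self, votes, positive, score):
        got_pos, got_score = consensus_from_votes(votes)
        assert got_pos == positive and got_score == pytest.approx(score)

    def test_unanimity_configurable(self):
        assert consensus_from_votes((1, 1, 0), majority=3)[0] is False

    def test_insufficient_positives_skipped(self, toy_lib, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            bundles = predict.train_mlm(toy_lib, seed=3, min_positives=10)
        assert bundles == {}
        assert any("skipped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# XPI

class TestXPI:
    def test_identical_sets_one_and_symmetry(self, toy_lib):
        tids, xpi = compute_xpi(toy_lib)
        assert np.allclose(xpi, xpi.T)
        assert all(xpi[i, i] == 1.0 for i in range(len(tids)))

    def test_disjoint_sets_zero(self, toy_lib):
        tids, xpi = compute_xpi(toy_lib)
        i, j = tids.index("T1"), tids.index("T2")
        assert xpi[i, j] == 0.0

    def test_overlap_formula(self):
        # |L_a| = 4, |L_b| = 8, overlap 1 → 0.25, via a constructed library
        import pandas as pd
        rows = []
        smis = ["C" * (i + 1) for i in range(11)]
        for i in range(4):
            rows.append((f"C{i}", smis[i], "A", "Kinase", "IC50", 10.0, "i", "s"))
        for i in range(3, 11):
            rows.append((f"C{i}", smis[i], "B", "Kinase", "IC50", 10.0, "i", "s"))
        df = pd.DataFrame(rows, columns=library.ACTIVITY_COLUMNS)
        comp = df[["compound_id", "smiles"]].drop_duplicates()
        comp = comp.assign(canonical_smiles=comp["smiles"], name=comp["compound_id"])
        targ = df[["target_id", "target_class"]].drop_duplicates()
        targ = targ.assign(gene_symbol=targ["target_id"], species="human")
        lib = library.from_frames(
            comp, targ, df[["compound_id", "target_id", "activity_type",
                            "value_nm", "moa", "source"]])
        tids, xpi = compute_xpi(lib)
        assert xpi[tids.index("A"), tids.index("B")] == pytest.approx(0.25)

    def test_propagation_floored_max(self):
        tids = ["A", "B"]
        xpi = np.array([[1.0, 0.5], [0.5, 1.0]])
        seeds = [MethodScore("XPI", "A", 0.8)]
        scores = {s.target_id: s.score
                  for s in predict_xpi(seeds, tids, xpi, floor=0.05)}
        assert scores == {"A": pytest.approx(0.8), "B": pytest.approx(0.4)}


# ---------------------------------------------------------------------------
# pipeline-level determinism

def test_predictor_deterministic_given_seed(toy_lib):
    q = chem.parse_smiles("Oc1ccc(CCC)cc1")
    outs = []
    for _ in range(2):
        p = predict.TargetPredictor(toy_lib, seed=11).fit()
        scores = p.predict_methods(q)
        outs.append({m: {t: s.score for t, s in per.items()}
                     for m, per in scores.items()})
    assert outs[0] == outs[1]
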
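"""Shared fixtures: the default synthetic study set, built once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from offtarget import chem, predict, synthetic

settings.register_profile(
    "deterministic", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def spec17() -> synthetic.SyntheticSpec:
    return synthetic.SyntheticSpec(seed=17)


@pytest.fixture(scope="session")
def lib17(spec17):
    lib, truth = synthetic.gen_reference_library(spec17)
    lib.build_descriptor_cache()
    return lib, truth


@pytest.fixture(scope="session")
def predictor17(lib17):
    lib, _ = lib17
    return predict.TargetPredictor(lib, seed=17).fit()


@pytest.fixture(scope="session")
def queries17(spec17, lib17):
    lib, _ = lib17
    return synthetic.gen_query_drugs(spec17, lib)


@pytest.fixture(scope="session")
def query_scores17(predictor17, queries17):
    """Six-method score maps for every held-out query, computed once."""
    out = {}
    for row in queries17.itertuples(index=False):
        mol = chem.parse_smiles(row.smiles, mol_id=row.query_id)
        out[row.query_id] = (predictor17.predict_methods(mol),
                             row.true_targets.split(";"))
    return out
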
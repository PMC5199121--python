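"""Shared fixtures: a small, fast synthetic compendium with known truth."""

import pandas as pd
import pytest

from phosphatlas import atlas, preprocess, synthetic
from phosphatlas.types import COMPENDIUM_COLUMNS, PhosphoCompendium


SMALL = synthetic.SimulationParams(
    n_kinases=10,
    n_conditions=24,
    n_sites=600,
    n_studies=4,
    sites_per_protein=4,
    substrates_per_kinase=10,
    n_complexes=8,
    complex_size_min=3,
    complex_size_max=5,
    tech_replicate_fraction=0.25,
    multiphospho_rate=0.05,
)


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.simulate_truth(SMALL, seed=7)


@pytest.fixture(scope="session")
def small_compendium(small_truth):
    return synthetic.simulate_compendium(small_truth, seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_compendium):
    matrix, _ = preprocess.run_preprocess(small_compendium, min_quant=30)
    return matrix


@pytest.fixture(scope="session")
def small_atlas(small_matrix, small_truth):
    return atlas.build_activity_matrix(
        small_matrix, small_truth.revealed_sets, min_hits=4, n_perm=500, seed=7
    )


@pytest.fixture(scope="session")
def small_flanks(small_truth):
    return synthetic.simulate_flanks(small_truth, seed=7)


def make_compendium(rows) -> PhosphoCompendium:
    """Build a compendium from (study, condition, rep, kind, site_token, mod_key, ratio) tuples."""
    from phosphatlas.types import SiteID

    records = []
    for study, cond, rep, kind, token, mod_key, ratio in rows:
        s = SiteID.parse(token)
        records.append(
            {
                "study": study,
                "condition": cond,
                "replicate": rep,
                "replicate_kind": kind,
                "protein": s.protein,
                "residue": s.residue,
                "position": s.position,
                "mod_key": mod_key,
                "log2_ratio": float(ratio),
            }
        )
    return PhosphoCompendium(pd.DataFrame(records, columns=COMPENDIUM_COLUMNS))
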
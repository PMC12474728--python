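import numpy as np
import pandas as pd
import pytest

import metabopanel as mp


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design synthetic cohort (46 cases, 138-control pool,
    626 metabolites, eight planted markers)."""
    cfg = mp.default_paper_config(seed=11)
    return mp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def matched_normalized(default_cohort):
    """The default cohort taken through matching and normalization: returns
    (normalized values DataFrame, boolean case indicator, subjects)."""
    subjects, matrix, _ = default_cohort
    matches = mp.match_cohort(subjects)
    analyzed = matches.case_ids + matches.control_ids
    norm = mp.normalize(mp.filter_endogenous(matrix).subset_samples(analyzed), subjects)
    is_case = (subjects.loc[norm.sample_ids, "group"] == "GDM").to_numpy()
    return norm, is_case, subjects


@pytest.fixture()
def toy_matrix():
    """Tiny annotated raw matrix: 5 endogenous, 3 xenobiotic, 1 partially
    characterized columns over 6 samples."""
    rng = np.random.default_rng(42)
    cols = [f"endo_{i}" for i in range(5)] + [f"x_{i}" for i in range(3)] + ["partial_0"]
    values = pd.DataFrame(
        rng.lognormal(mean=10, sigma=1, size=(6, 9)),
        index=[f"s{i}" for i in range(6)],
        columns=cols,
    )
    annotations = pd.DataFrame(
        {
            "metabolite": cols,
            "category": ["endogenous"] * 5 + ["xenobiotic"] * 3
            + ["partially_characterized"],
            "pathway": ["p"] * 9,
        }
    ).set_index("metabolite")
    return mp.MetaboliteMatrix(values=values, annotations=annotations, state="raw")


@pytest.fixture()
def toy_subjects(toy_matrix):
    rng = np.random.default_rng(7)
    ids = list(toy_matrix.values.index)
    return pd.DataFrame(
        {
            "id": ids,
            "group": ["GDM"] * 3 + ["CON"] * 3,
            "age": rng.normal(32, 4, 6).round(1),
            "bmi": rng.normal(30, 6, 6).round(1),
            "ga1": rng.normal(12, 3, 6).round(1),
            "ga2": rng.normal(30, 3, 6).round(1),
            "osmolality": rng.uniform(300, 800, 6).round(1),
        },
        index=ids,
    )
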
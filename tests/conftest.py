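import numpy as np
import pandas as pd
import pytest

import seqdoe as sq


@pytest.fixture(scope="session")
def study_factors():
    return sq.pca_factors()


@pytest.fixture(scope="session")
def truth():
    return sq.default_pca_truth()


@pytest.fixture(scope="session")
def res4_design(study_factors):
    """32-run resolution IV screening design with the genetic factors
    assigned columns that project onto a full strain factorial."""
    spec = sq.DesignSpec(study_factors, resolution_request="IV")
    design = sq.generate_design(spec)
    genetic = [f.name for f in study_factors if f.category == "genetic"]
    assigned, _ = sq.assign_columns(spec, design, genetic)
    return assigned


@pytest.fixture(scope="session")
def res5_design(study_factors, truth):
    """64-run resolution V refinement design over the 8 factors left active
    after fixing PAL-C4H, pH and Phe."""
    fixed = {"PAL-C4H": 1, "pH": -1, "Phe": 1}
    active = tuple(f for f in study_factors if f.name not in fixed)
    spec = sq.DesignSpec(active, resolution_request="V")
    return sq.generate_design(spec)


@pytest.fixture(scope="session")
def conditional_truth(truth):
    return truth.conditional({"PAL-C4H": 1, "pH": -1, "Phe": 1})


def full_22_responses():
    """Full 2^2 factorial with y = (1, 3, 5, 7) at (--, +-, -+, ++)."""
    design = sq.generate_design(sq.spec_from_names(["A", "B"]))
    order = {(-1, -1): 1.0, (1, -1): 3.0, (-1, 1): 5.0, (1, 1): 7.0}
    y = [order[tuple(int(v) for v in row)] for row in design.runs]
    responses = pd.DataFrame(
        {
            "run_id": design.run_ids,
            "replicate": 1,
            "response_mg_per_L": y,
        }
    )
    return design, responses


@pytest.fixture
def interpolation_case():
    return full_22_responses()
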
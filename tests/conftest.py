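import warnings

import numpy as np
import pytest

from coimeta.meta import StudyEffect
from coimeta.synthetic import (
    SmallCollectionWarning,
    simulate_expression_studies,
    table1_like_study_specs,
)

GENES = tuple(f"GENE{i:02d}" for i in range(10))
PLANTED = {"GENE00": 1.0, "GENE01": -1.5}


def make_effects(ys, vs, gene="g", n=5):
    return [
        StudyEffect(gene=gene, study_id=f"s{i + 1}", lfc=float(y), variance=float(v),
                    n_case=n, n_control=n)
        for i, (y, v) in enumerate(zip(ys, vs))
    ]


def six_studies(planted=None, tau=0.0, noise_sd=0.5, seed=0, genes=GENES):
    """Six small case/control studies with the emulated collection's layout."""
    specs = table1_like_study_specs(
        genes, planted if planted is not None else PLANTED, tau=tau, noise_sd=noise_sd, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallCollectionWarning)
        return simulate_expression_studies(specs)


@pytest.fixture
def studies():
    return six_studies()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
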
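import numpy as np
import pytest

from mitodemes.coalsim import (
    DemographicModel,
    ModelTemplate,
    Prior,
    SampleGroup,
    SamplingScheme,
)
from mitodemes.mito_data import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_alignment():
    """5 sequences, 10 columns, with known differences."""
    seqs = [
        "ACGTACGTAC",
        "ACGTACGTAC",
        "ACGTACGTAT",
        "ACGAACGTAC",
        "TCGTACGTAC",
    ]
    return Alignment.from_sequences([f"s{i}" for i in range(5)], seqs)


def single_deme_template(
    name: str,
    ne_prior: Prior,
    n_per_pop: int = 10,
    n_pops: int = 2,
    pop_prefix: str = "pop",
) -> ModelTemplate:
    """One-deme model sampled as ``n_pops`` modern populations (so that the
    full summary vector, including pairwise statistics, is defined)."""
    groups = [SampleGroup(f"{pop_prefix}{i + 1}", "deme0", n_per_pop) for i in range(n_pops)]

    def builder(params):
        return DemographicModel(demes={"deme0": [(0.0, params["ne"])]})

    return ModelTemplate(
        name=name,
        priors={"ne": ne_prior},
        scheme=SamplingScheme(groups),
        builder=builder,
    )


#: Representative parameter values for a forager/farmer replacement
#: demography: moderate island sizes with a small, drifted forager deme.
#: Used as the generating truth in pseudo-observed recovery experiments.
REPLACEMENT_PARAMS = {
    "ne_sicily": 3000.0,
    "ne_ancestral": 5000.0,
    "ne_phoenician": 2000.0,
    "ne_greek": 2000.0,
    "ne_islamic": 2000.0,
    "ne_forager": 800.0,
    "ne_incoming": 800.0,
}


def fixed_replacement_template(sample_scale: float = 1.0) -> ModelTemplate:
    from mitodemes.coalsim import model_library

    template = model_library("C", sample_scale=sample_scale)
    template.priors = {k: Prior("fixed", v) for k, v in REPLACEMENT_PARAMS.items()}
    return template
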
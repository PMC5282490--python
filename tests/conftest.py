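"""Shared fixtures: default model parameters and a small synthetic family."""

import pytest

from probmsa.pipeline import PipelineConfig, run_pipeline
from probmsa.posterior import PairHmmParams, PartitionParams
from probmsa.refinement import RefinementConfig
from probmsa.testkit import FamilySpec, generate_family


@pytest.fixture(scope="session")
def hmm_params():
    return PairHmmParams.default()


@pytest.fixture(scope="session")
def part_params():
    return PartitionParams()


@pytest.fixture(scope="session")
def small_family():
    """6 sequences, ancestor length 40: (sequences, true alignment, tree)."""
    return generate_family(FamilySpec(n=6, ancestor_length=40, seed=11))


@pytest.fixture(scope="session")
def small_pipeline(small_family):
    seqs, truth, tree = small_family
    cfg = PipelineConfig(seed=11,
                         refinement=RefinementConfig(iterations=0, seed=11))
    return seqs, truth, tree, run_pipeline(seqs, cfg)
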
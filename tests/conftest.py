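import numpy as np
import pytest
from hypothesis import settings

from csrnai import extract_psf_rules, load_nn_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def nn_table():
    return load_nn_table()


@pytest.fixture(scope="session")
def rule_training_sets():
    """Small deterministic positive/negative 19-mer sets with planted signal."""
    rng = np.random.default_rng(1234)
    def draw(bias_nt):
        out = []
        for _ in range(60):
            s = list("".join(rng.choice(list("ACGT"), size=19)))
            if rng.random() < 0.8:
                s[2] = bias_nt
            out.append("".join(s))
        return out
    return draw("A"), draw("C")


@pytest.fixture(scope="session")
def psf_rules(rule_training_sets):
    pos, neg = rule_training_sets
    return extract_psf_rules(pos, neg, mode="single", k=20)


@pytest.fixture(scope="session")
def spsf_rules(rule_training_sets):
    pos, neg = rule_training_sets
    return extract_psf_rules(pos, neg, mode="dinucleotide", k=16)
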
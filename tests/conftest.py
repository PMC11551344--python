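import numpy as np
import pytest
from hypothesis import settings

from coevjac import Alphabet

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def alphabet() -> Alphabet:
    return Alphabet()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def write_fasta_file(tmp_path):
    """Write records to a temporary FASTA/A3M file and return its path."""

    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


class CountingModel:
    """LogitModel wrapper counting evaluate calls (contract test helper)."""

    def __init__(self, inner):
        self.inner = inner
        self.supports_soft = getattr(inner, "supports_soft", False)
        self.n_calls = 0

    def evaluate(self, tokens):
        self.n_calls += 1
        return self.inner.evaluate(tokens)

    def evaluate_soft(self, distribution):
        self.n_calls += 1
        return self.inner.evaluate_soft(distribution)


@pytest.fixture()
def counting_model():
    return CountingModel
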
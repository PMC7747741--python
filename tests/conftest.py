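import numpy as np
import pytest

from methsig import GeneMatrix, SyntheticSpec, generate, small_preset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_gene_matrix(values, groups=None, prefix="G"):
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i + 1:04d}" for i in range(values.shape[0])]
    samples = [f"S{j + 1:03d}" for j in range(values.shape[1])]
    if groups == "half":
        half = values.shape[1] // 2
        groups = {s: ("case" if j < half else "control")
                  for j, s in enumerate(samples)}
    return GeneMatrix(genes, samples, values, groups)


@pytest.fixture(scope="session")
def small_synthetic():
    """One small-preset dataset shared across the suite (seed fixed)."""
    spec = small_preset(seed=1)
    beta, ann, truth = generate(spec)
    return spec, beta, ann, truth
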
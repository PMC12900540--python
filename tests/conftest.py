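import numpy as np
import pytest

from stransfer.io_preprocess import STSlice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_slice():
    """3 spots x 2 genes with two region labels."""
    return STSlice(
        expression=np.array([[1.0, 0.0], [2.0, 3.0], [0.0, 5.0]]),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        spot_ids=np.array(["s1", "s2", "s3"], dtype=object),
        gene_ids=np.array(["gA", "gB"], dtype=object),
        labels=np.array(["L1", "L1", "L2"], dtype=object),
        slice_id="toy",
    )


def random_slice(rng, n=20, g=8, labeled=True, slice_id="rand"):
    """Small random slice for plumbing tests (not a model of anything)."""
    return STSlice(
        expression=rng.poisson(3.0, size=(n, g)).astype(float),
        coords=rng.uniform(0, 10, size=(n, 2)),
        spot_ids=np.array([f"{slice_id}_{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(g)], dtype=object),
        labels=(
            np.array([f"R{i % 2}" for i in range(n)], dtype=object) if labeled else None
        ),
        slice_id=slice_id,
    )
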
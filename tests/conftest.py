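"""Shared fixtures: a small synthetic benchmark and a quickly trained model.

The benchmark here is deliberately smaller than the package defaults
(4 compounds per family, 64 px images, 32 px network input) so the unit
suite stays fast; the full default-size benchmark is exercised in the
end-to-end acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from chemsiam import (
    TripletConfig,
    make_benchmark,
    mine_triplets,
    similarity_matrix,
)
from chemsiam.io import read_manifest
from chemsiam.model import TripletEmbedder
from chemsiam.samples import build_samples

SEED = 7
INPUT_SIZE = 32


@pytest.fixture(scope="session")
def bench_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bench")
    make_benchmark(out, per_family=4, seed=SEED, size=64)
    return out


@pytest.fixture(scope="session")
def bench(bench_dir):
    compounds = read_manifest(bench_dir / "manifest.csv")
    sim = similarity_matrix(compounds)
    triplets = mine_triplets(sim, TripletConfig())
    samples = build_samples(compounds, input_size=INPUT_SIZE)
    return {
        "dir": bench_dir,
        "compounds": compounds,
        "sim": sim,
        "triplets": triplets,
        "samples": samples,
    }


@pytest.fixture(scope="session")
def trained(bench):
    est = TripletEmbedder(
        input_size=INPUT_SIZE, max_epochs=3, patience=3, seed=SEED
    ).fit(bench["samples"], triplets=bench["triplets"])
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
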
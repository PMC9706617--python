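"""Shared fixtures: tiny trees, grids and a cached recovery sweep."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from phyloniche import synthetic_data as sim
from phyloniche.data_io import EnvLayer, Phylo, read_newick


@pytest.fixture()
def newick_file(tmp_path):
    """Factory writing a Newick string to a temp file."""

    def _write(text: str):
        path = tmp_path / "tree.nwk"
        path.write_text(text + "\n")
        return path

    return _write


@pytest.fixture()
def cherry(newick_file) -> Phylo:
    return read_newick(newick_file("(A:1,B:1):0;"))


@pytest.fixture()
def quartet(newick_file) -> Phylo:
    return read_newick(newick_file("((A:1,B:1):2,(C:1,D:1):2):0;"))


@pytest.fixture()
def flat_layer() -> EnvLayer:
    """10x10 one-degree grid of constant 5.0, no nodata."""
    return EnvLayer(
        values=np.full((10, 10), 5.0),
        nodata_mask=np.zeros((10, 10), dtype=bool),
        extent=(0.0, 10.0, 0.0, 10.0),
        resolution=60.0,
        variable_id="temperature",
    )


@pytest.fixture()
def gradient_layer() -> EnvLayer:
    return sim.make_env_layer(
        extent=(-30.0, 30.0, -60.0, 60.0),
        resolution=60.0,
        kind="latitudinal_gradient",
        value_range=(-5.0, 33.0),
        variable_id="temperature",
    )


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylo:
    """Small random ultrametric tree for oracle comparisons."""
    return sim.simulate_tree(n_tips, root_age=float(rng.uniform(1.0, 10.0)),
                             seed=int(rng.integers(2**31)))


@pytest.fixture(scope="session")
def recovery_sweep():
    """Recovery scores on 20 default synthetic datasets (seeds 1..20).

    Session-scoped because the sweep is the most expensive computation
    in the suite and several tests consume different columns of it.
    """
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 21):
            ds = sim.build_dataset(seed=seed)
            results.append(sim.evaluate_recovery(ds, trim_level=1.0, method="parsimony"))
    return results
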
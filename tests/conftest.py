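import logging

import numpy as np
import pandas as pd
import pytest

from commdrivers.containers import BlockCollection, SiteSpeciesMatrix

logging.getLogger("commdrivers").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_community(values, species=None, trophic="plant", guilds=None,
                   hosts=None, sites=None):
    """Small SiteSpeciesMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    n, q = values.shape
    species = species or [f"sp{j}" for j in range(q)]
    sites = sites or [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "trophic_group": trophic if isinstance(trophic, list) else [trophic] * q,
            "guild": guilds or ["none"] * q,
            "host_genera": hosts or [""] * q,
        },
        index=species,
    )
    return SiteSpeciesMatrix(pd.DataFrame(values, index=sites, columns=species), meta)


def make_blocks(rng, n, widths, prefix="B"):
    blocks = {}
    for k, w in enumerate(widths):
        name = f"{prefix}{k}"
        blocks[name] = pd.DataFrame(
            rng.standard_normal((n, w)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"{name}_v{j}" for j in range(w)],
        )
    return BlockCollection(blocks)


@pytest.fixture
def community(rng):
    return make_community(rng.uniform(0, 10, size=(8, 5)))
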
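import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nucspread.model import CONNECTIVITY_LAYOUTS, ModelConfig, RateSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_config(
    n=6,
    mechanism="combined",
    enzymes="single_mt",
    connectivity=(),
    **rates,
) -> ModelConfig:
    """Small config with reference rates and centred initiation sites."""
    if enzymes == "single_mt":
        sites = {"Mt": (n + 1) // 2}
    else:
        sites = {"Mt": 1, "At": n}
    return ModelConfig(
        n=n,
        mechanism=mechanism,
        enzymes=enzymes,
        initiation_sites=sites,
        connectivity_sites=connectivity,
        rates=RateSet.table1(enzymes, **rates),
        initial_state="all_U_empty",
    )


def all_variants(n=6):
    """Every mechanism/enzyme combination (plus one connectivity layout)."""
    variants = []
    for mechanism in ("diffusion", "recruitment", "combined"):
        for enzymes in ("single_mt", "dual"):
            variants.append(make_config(n=n, mechanism=mechanism, enzymes=enzymes))
    variants.append(
        make_config(n=6, mechanism="combined", enzymes="dual", connectivity=(2, 4, 6))
    )
    return variants
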
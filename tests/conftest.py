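import random

import dendropy
import pandas as pd
import pytest

from nicheshift.niche import NicheRecord, build_catalog


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        rooting="default-rooted",
    )


@pytest.fixture
def simple_ultrametric():
    """((a:1,b:1):1,c:2); — one cherry at relative height 0.5."""
    return tree_from_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def rng():
    return random.Random(20100901)


@pytest.fixture
def willow_records():
    """Six-species niche table with a generalist and an outgroup."""
    return [
        NicheRecord("sp1", "external_folivory", frozenset({"Salix"})),
        NicheRecord("sp2", "external_folivory", frozenset({"Salix", "Betula"})),
        NicheRecord("sp3", "galling", frozenset({"Salix"})),
        NicheRecord("sp4", "external_folivory", frozenset({"Betula"})),
        NicheRecord("sp5", "external_folivory", frozenset({"Salix"})),
        NicheRecord("out1", "", frozenset({"?"}), is_outgroup=True),
    ]


@pytest.fixture
def willow_coding(willow_records):
    return build_catalog(willow_records)


@pytest.fixture
def pair_dataset_19_16():
    """35 sister pairs, 19 niche-different, ages spread over [0, 1]."""
    rows = []
    r = random.Random(35)
    for i in range(35):
        rows.append(
            {
                "tip_a": f"a{i}", "tip_b": f"b{i}",
                "split_age": round(r.uniform(0.0, 1.0), 4),
                "niche_different": 1 if i < 19 else 0,
            }
        )
    return pd.DataFrame(rows)
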
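import io

import pytest

from enzpat.pipeline import run_pipeline
from enzpat.sequence_db import parse_flatfile
from enzpat.synthetic import benchmark_database


@pytest.fixture(scope="session")
def benchmark_db():
    """The canonical synthetic study: 5 families (8 members, 8% substitution),
    20 putative decoys, 50 non-enzymes, 2 multidomain concatenations."""
    return benchmark_database(seed=1)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_db):
    raw = parse_flatfile(io.StringIO(benchmark_db.flatfile_text))
    return run_pipeline(raw)


@pytest.fixture(scope="session")
def node_index(benchmark_result):
    """node_id -> (tree_id, ClusterNode) over the whole forest."""
    index = {}
    for idx, tree in enumerate(benchmark_result.forest.all_trees):
        tree_id = benchmark_result.tree_ids[idx]
        for node in tree.walk():
            index[node.node_id] = (tree_id, node)
    return index
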
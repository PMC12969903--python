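import pytest

from pangsv import (
    AssemblyPath,
    PangenomeGraph,
    Segment,
    SimConfig,
    simulate_all,
)


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic pangenome shared (read-only) across tests."""
    return simulate_all(SimConfig(seed=7, n_animals=2000))


@pytest.fixture(scope="session")
def called(bundle):
    """Bubbles, SV records, partition, NRUI panel and PAV matrix from the
    shared bundle."""
    from pangsv import (
        extract_nruis,
        find_bubbles,
        genotype_pav,
        partition_segments,
        records_from_bubbles,
    )

    bubbles = find_bubbles(bundle.graph, bundle.paths)
    records = records_from_bubbles(bubbles, bundle.paths)
    partition = partition_segments(bundle.graph, bundle.paths)
    panel = extract_nruis(bundle.graph, bubbles, partition, bundle.paths)
    pav = genotype_pav(panel, bundle.paths)
    return {
        "bubbles": bubbles,
        "records": records,
        "partition": partition,
        "panel": panel,
        "pav": pav,
    }


def linear_graph(n_segments: int = 3, seg_len: int = 60) -> PangenomeGraph:
    """chr1 = s1..sN of ``seg_len`` each, all on the reference path."""
    graph = PangenomeGraph()
    base = "ACGT" * (seg_len // 4)
    for i in range(n_segments):
        graph.add_segment(Segment(f"s{i + 1}", base))
    for i in range(n_segments - 1):
        graph.add_link(f"s{i + 1}", "+", f"s{i + 2}", "+")
    graph.reference_path["chr1"] = [(f"s{i + 1}", "+") for i in range(n_segments)]
    return graph


def path_for(graph: PangenomeGraph, sample: str, walk, breed: str = "X") -> AssemblyPath:
    return AssemblyPath(sample=sample, breed=breed, walks={"chr1": list(walk)})
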
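import numpy as np
import pytest

from lsvkit.simulate import make_annotation, make_gene, make_panel
from lsvkit.splicegraph import BuildGroup, Candidate, parse_annotation, update_splicegraph


@pytest.fixture(scope="session")
def panel_specs():
    return make_panel(20)


@pytest.fixture(scope="session")
def panel_gff3(tmp_path_factory, panel_specs):
    path = tmp_path_factory.mktemp("panel") / "genes.gff3"
    make_annotation(panel_specs, str(path))
    return str(path)


@pytest.fixture(scope="session")
def panel_graphs(panel_gff3, panel_specs):
    """Panel splicegraphs with the planted de novo junctions incorporated."""
    graphs = parse_annotation(panel_gff3)
    groups = [BuildGroup("g", ["s0", "s1"], 2)]
    for spec in panel_specs:
        cands = [
            Candidate("junction", s, e, {"s0": (20.0, 5), "s1": (20.0, 5)})
            for s, e, _ in spec.denovo_junctions
        ]
        if cands:
            graphs[spec.gene_id] = update_splicegraph(
                graphs[spec.gene_id], cands, groups
            )
    return graphs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
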
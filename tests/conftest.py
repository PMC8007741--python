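import numpy as np
import pandas as pd
import pytest

from diapausetx import de as de_mod
from diapausetx import expression as expr_mod
from diapausetx import simulate as sim_mod
from diapausetx.ontology import go_filter_transcripts


@pytest.fixture(scope="session")
def default_dataset():
    """The study-condition emulation: 16 samples, planted effects, modules,
    indicators and congener contamination (generator defaults, seed 42)."""
    config = sim_mod.SimulationConfig()
    counts, catalog, samples, truth = sim_mod.generate_dataset(config)
    return config, counts, catalog, samples, truth


@pytest.fixture(scope="session")
def default_ontology(default_dataset):
    config, _, _, _, truth = default_dataset
    return sim_mod.generate_ontology(config, truth)


@pytest.fixture(scope="session")
def default_ladder(default_dataset):
    _, counts, catalog, _, _ = default_dataset
    return expr_mod.normalization_ladder(counts, catalog)


@pytest.fixture(scope="session")
def default_de(default_dataset):
    _, counts, _, samples, _ = default_dataset
    return de_mod.run_de(counts, samples)


@pytest.fixture(scope="session")
def default_deg_sets(default_dataset, default_ontology, default_de):
    """DEGs intersected with the three indicator-panel GO filters."""
    _, _, _, _, truth = default_dataset
    graph, annotation = default_ontology
    _, degs = default_de
    out = {}
    for tag in ("oogenesis_like", "fatty_acid_like", "rna_metabolism_like"):
        term = sim_mod.tag_term(tag)
        members = go_filter_transcripts(annotation, graph, term)
        out[term] = sorted(set(members) & set(degs))
    return out


@pytest.fixture()
def toy_counts():
    """Small handmade count matrix with known lengths."""
    counts = pd.DataFrame(
        {
            "s1": [100, 0, 400],
            "s2": [50, 150, 300],
        },
        index=["t1", "t2", "t3"],
    )
    catalog = pd.DataFrame(
        {
            "length_bp": [1000, 2000, 500],
            "annotation": [pd.NA] * 3,
            "go_terms": [frozenset()] * 3,
            "cross_map_flag": [False] * 3,
        },
        index=pd.Index(["t1", "t2", "t3"], name="transcript_id"),
    )
    return counts, catalog


def sixteen_sample_table() -> pd.DataFrame:
    rows = []
    for g in expr_mod.GROUP_ORDER:
        for r in range(4):
            rows.append(
                {
                    "sample_id": f"{g}_{r + 1}",
                    "source": "field" if g in ("EF", "LF") else "culture",
                    "timepoint": "early" if g.startswith("E") else "late",
                    "group": g,
                    "replicate": r + 1,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture()
def sample_table():
    return sixteen_sample_table()
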
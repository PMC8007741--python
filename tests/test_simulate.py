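"""Synthetic-data generator: determinism, planted truth bookkeeping,
ontology realization and contamination injection."""

import numpy as np
import pandas as pd
import pytest

from diapausetx import simulate as sim
from diapausetx.ontology import go_filter_transcripts


def test_shape_follows_config():
    cfg = sim.SimulationConfig(n_transcripts=500, tag_sizes=(), effect_blocks=(),
                               modules=(), indicators=(), contamination=None)
    counts, catalog, samples, _ = sim.generate_dataset(cfg)
    assert counts.shape == (500, 16)
    assert len(catalog) == 500
    assert list(counts.columns) == list(samples.index)
    assert (catalog["length_bp"] >= 1).all()


def test_identical_seed_reproduces_identical_outputs():
    cfg = sim.SimulationConfig(
        n_transcripts=400,
        tag_sizes=(("oogenesis_like", 60), ("fatty_acid_like", 20),
                   ("rna_metabolism_like", 100)),
        effect_blocks=(sim.EffectBlock("rna_metabolism_like", ("EF", "LF"), -0.3),),
        modules=(sim.ModuleSpec("m", 50, None, (("LC", 2.0),)),),
        indicators=(sim.IndicatorSpec("field_up", (("fatty_acid_like", 5),)),),
        contamination=sim.ContaminationSpec(proportions=(("EF_1", 0.3),),
                                            n_prone=30),
    )
    a, cat_a, _, truth_a = sim.generate_dataset(cfg, seed=7)
    b, cat_b, _, truth_b = sim.generate_dataset(cfg, seed=7)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(cat_a, cat_b)
    assert truth_a.indicator_ids == truth_b.indicator_ids
    c, _, _, _ = sim.generate_dataset(cfg, seed=8)
    assert not a.equals(c)


def test_null_config_has_empty_truth():
    _, _, _, truth = sim.generate_dataset(sim.null_config(seed=2))
    assert all(len(v) == 0 for v in truth.de_labels.values())
    assert (truth.module_labels == "0").all()
    assert truth.indicator_ids == {}


def test_field_up_indicator_effect_recovered(default_dataset, default_ladder):
    """Group-mean log2 ratio of planted field-up indicators lands within
    +/-0.3 of the configured effect (seed 42 defaults)."""
    config, counts, _, samples, truth = default_dataset
    rpkm = default_ladder["rpkm"].values
    field = samples.index[samples["source"] == "field"]
    culture = samples.index[samples["source"] == "culture"]
    ids = sorted(truth.indicator_ids["field_up"])
    ratio = np.log2(rpkm.loc[ids, field].mean(axis=1)
                    / rpkm.loc[ids, culture].mean(axis=1))
    configured = config.indicators[0].log2fc
    assert float(ratio.mean()) == pytest.approx(configured, abs=0.3)


def test_truth_ids_exist_and_are_disjoint(default_dataset):
    _, counts, _, _, truth = default_dataset
    all_ids = set(counts.index)
    f = truth.indicator_ids["field_up"]
    c = truth.indicator_ids["culture_up"]
    assert f <= all_ids and c <= all_ids
    assert not (f & c)
    assert truth.contaminated_ids <= all_ids
    for members in truth.tag_members.values():
        assert members <= all_ids


def test_invalid_configs_raise():
    with pytest.raises(ValueError, match="replicates"):
        sim.SimulationConfig(replicates=1)
    with pytest.raises(ValueError, match="unknown tag"):
        sim.SimulationConfig(tag_sizes=(("a", 5),),
                             effect_blocks=(sim.EffectBlock("b", ("EF",), 1.0),),
                             modules=(), indicators=(), contamination=None)
    with pytest.raises(ValueError, match="exceed"):
        sim.SimulationConfig(n_transcripts=10, tag_sizes=(("a", 50),),
                             effect_blocks=(), modules=(), indicators=(),
                             contamination=None)
    with pytest.raises(ValueError, match="finite"):
        sim.SimulationConfig(
            tag_sizes=(("a", 5),),
            effect_blocks=(sim.EffectBlock("a", ("EF",), np.inf),),
            modules=(), indicators=(), contamination=None)


def test_generated_ontology_is_acyclic_with_single_root(default_dataset,
                                                        default_ontology):
    import networkx as nx

    graph, annotation = default_ontology
    assert nx.is_directed_acyclic_graph(graph.graph)
    roots = [n for n in graph.graph.nodes if graph.graph.out_degree(n) == 0]
    assert roots == [sim.ROOT_TERM[0]]
    # every annotated term is declared
    for terms in annotation.values():
        assert terms <= graph.terms


def test_ontology_zero_sized_tag_gives_empty_closure():
    cfg = sim.SimulationConfig(n_transcripts=100,
                               tag_sizes=(("oogenesis_like", 0),),
                               effect_blocks=(), modules=(), indicators=(),
                               contamination=None)
    graph, annotation = sim.generate_ontology(cfg)
    term = sim.tag_term("oogenesis_like")
    assert go_filter_transcripts(annotation, graph, term) == frozenset()


def _contamination_inputs(n=300, seed=3):
    cfg = sim.SimulationConfig(n_transcripts=n, tag_sizes=(), effect_blocks=(),
                               modules=(), indicators=(), contamination=None,
                               seed=seed)
    counts, catalog, samples, _ = sim.generate_dataset(cfg)
    return counts, catalog, samples


def test_contamination_zero_proportions_leave_counts_unchanged():
    counts, catalog, samples = _contamination_inputs()
    props = pd.Series(0.0, index=counts.columns)
    out, markers, update = sim.inject_contamination(counts, catalog, props,
                                                    seed=1)
    pd.testing.assert_frame_equal(out, counts)
    assert (markers["C_glacialis"] == 0).all()
    assert (markers["C_finmarchicus"] > 0).all()


def test_contamination_preserves_library_size_and_targets_prone_set():
    counts, catalog, samples = _contamination_inputs()
    props = pd.Series(0.0, index=counts.columns)
    props.iloc[0] = 0.32
    spec = sim.ContaminationSpec(proportions=tuple(props.items()), n_prone=10)
    out, markers, update = sim.inject_contamination(counts, catalog, props,
                                                    efficiency=0.30, seed=1,
                                                    spec=spec)
    assert out.sum().equals(counts.sum())
    changed = out.index[(out.iloc[:, 0] != counts.iloc[:, 0])]
    prone = update["contaminated_ids"]
    # expected contaminated fraction 0.32 * 0.30 = 0.096 of the library
    added = (out.loc[sorted(prone)].iloc[:, 0]
             - counts.loc[sorted(prone)].iloc[:, 0]).clip(lower=0).sum()
    total = counts.iloc[:, 0].sum()
    assert added / total == pytest.approx(0.096, abs=0.02)
    assert update["congener_truth"].iloc[0] == 0.32


def test_contamination_rejects_bad_proportions():
    counts, catalog, _ = _contamination_inputs()
    props = pd.Series(1.5, index=counts.columns)
    with pytest.raises(ValueError):
        sim.inject_contamination(counts, catalog, props)


def test_write_dataset_roundtrips_inputs(tmp_path, default_dataset,
                                         default_ontology):
    from diapausetx import expression as ex
    from diapausetx.ontology import parse_obo

    config, counts, catalog, samples, truth = default_dataset
    graph, annotation = default_ontology
    sim.write_dataset(tmp_path, counts, catalog, samples, truth, graph,
                      annotation)
    c, cat, s = ex.read_counts(tmp_path / "counts.tsv", tmp_path / "catalog.tsv",
                               tmp_path / "samples.tsv")
    pd.testing.assert_frame_equal(c, counts)
    g2 = parse_obo(tmp_path / "ontology.obo")
    assert g2.terms == graph.terms
    assert (tmp_path / "truth.json").exists()
    assert (tmp_path / "markers.tsv").exists()


def test_planted_module_genes_correlate_above_background():
    _, counts, catalog, _, truth = (
        sim.module_recovery_config(seed=5),
        *sim.generate_dataset(sim.module_recovery_config(seed=5)),
    )[:5]
    from diapausetx import expression as ex

    log2 = ex.log_transform(ex.compute_rpkm(counts, catalog)).values
    z = log2.sub(log2.mean(axis=1), axis=0).div(log2.std(axis=1, ddof=1), axis=0)
    corr = np.corrcoef(z.to_numpy())
    corr = pd.DataFrame(np.abs(corr), index=z.index, columns=z.index)
    m1 = truth.module_labels.index[truth.module_labels == "m1"]
    bg = truth.module_labels.index[truth.module_labels == "0"]
    within = corr.loc[m1, m1].to_numpy()[np.triu_indices(len(m1), 1)].mean()
    between = corr.loc[m1, bg].to_numpy().mean()
    assert within > between + 0.3
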
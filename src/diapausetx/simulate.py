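"""Synthetic count data with known planted truth.

The generator emulates the study design the workflow targets: 16 bulk
RNA-seq samples in four groups (EF, LF = early/late field on the diapause
program; EC, LC = early/late culture on the reproductive program) with 4
replicates each.  Counts are negative binomial (Var = mu + phi mu^2, phi
per transcript); a program effect is concentrated in GO-tagged gene sets
(an "RNA metabolic process"-like set down in field, a fatty-acid-like set
up in field), a maturation effect separates EC from LC (an oogenesis-like
set up in LC), co-expression modules are realized as shared latent
group-varying factors, strict-separation indicator genes are planted with
large, low-dispersion effects, and congener read contamination with
mtCOI-like markers is injected by re-attributing reads (library size
preserved).

Every function is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import expression as expr_mod
from .ontology import OntologyGraph, write_obo

# GO-style ids for the synthetic tags; parent terms reuse the familiar
# accessions of the processes they emulate, child terms are synthetic.
TAG_TERMS = {
    "oogenesis_like": ("GO:0048477", "oogenesis-like"),
    "lipid_storage_like": ("GO:0019915", "lipid-storage-like"),
    "fatty_acid_like": ("GO:0006633", "fatty-acid-biosynthesis-like"),
    "rna_metabolism_like": ("GO:0016070", "RNA-metabolic-process-like"),
}
ROOT_TERM = ("GO:0008150", "biological_process")
OTHER_TERM = ("GO:0009987", "cellular-process-like")

FIELD_GROUPS = ("EF", "LF")
CULTURE_GROUPS = ("EC", "LC")


@dataclass(frozen=True)
class EffectBlock:
    """A log2 fold-change applied to a span of a tag's transcripts in the
    affected groups (relative to the remaining groups).

    ``span`` selects a fractional range of the tag's members, so one tag
    can mix up- and down-regulated genes (as real process-level responses
    do), which also keeps library composition roughly balanced.
    """

    tag: str
    groups: tuple[str, ...]
    log2fc: float
    span: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: shared latent factor with
    group-specific levels, per-sample jitter and per-gene loadings.

    ``mixed_loadings`` flips the sign of half the loadings at random;
    unsigned co-expression networks group anti-correlated genes together,
    and sign balance keeps the module from distorting library composition.
    """

    name: str
    size: int
    tag: str | None  # None = background transcripts
    levels: tuple[tuple[str, float], ...]  # group -> factor level (log2 units)
    loading_mean: float = 0.8
    loading_sd: float = 0.1
    jitter_sd: float = 0.4
    mixed_loadings: bool = True


@dataclass(frozen=True)
class IndicatorSpec:
    """Strict-separation indicator genes: large program effect (several
    generator SDs) at capped dispersion, drawn from the named tags."""

    direction: str  # field_up | culture_up
    per_tag: tuple[tuple[str, int], ...]
    log2fc: float = 3.0
    dispersion: float = 0.05
    min_mean_count: int = 50


@dataclass(frozen=True)
class ContaminationSpec:
    """Per-sample congener proportions and the cross-mapping efficiency."""

    proportions: tuple[tuple[str, float], ...]  # sample -> congener share
    efficiency: float = 0.30
    n_prone: int = 600
    marker_total: int = 10_000
    focal_species: str = "C_finmarchicus"
    congener_species: str = "C_glacialis"


@dataclass(frozen=True)
class SimulationConfig:
    n_transcripts: int = 4000
    groups: tuple[str, ...] = expr_mod.GROUP_ORDER
    replicates: int = 4
    baseline_logmean_mean: float = 0.0  # log2 relative abundance
    baseline_logmean_sd: float = 1.2
    dispersion_shape: float = 4.0
    dispersion_mean: float = 0.1
    length_range: tuple[int, int] = (300, 10_000)
    library_size_mean: float = 1e6
    library_size_sigma: float = 0.1
    tag_sizes: tuple[tuple[str, int], ...] = (
        ("oogenesis_like", 584),
        ("lipid_storage_like", 717),
        ("fatty_acid_like", 70),
        ("rna_metabolism_like", 1064),
    )
    effect_blocks: tuple[EffectBlock, ...] = (
        EffectBlock("rna_metabolism_like", FIELD_GROUPS, -0.3),
        EffectBlock("fatty_acid_like", FIELD_GROUPS, 0.4),
        EffectBlock("lipid_storage_like", FIELD_GROUPS, 0.3),
        # somewhat more than half of the maturation-responsive genes up in
        # LC, the rest down, so library composition stays balanced
        EffectBlock("oogenesis_like", ("LC",), 1.8, span=(0.0, 0.6)),
        EffectBlock("oogenesis_like", ("LC",), -1.8, span=(0.6, 1.0)),
    )
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec("storage", 250, "lipid_storage_like",
                   (("EF", 1.0), ("LF", 1.0), ("EC", -1.0), ("LC", -1.0))),
        ModuleSpec("maturation", 250, None,
                   (("EF", -0.6), ("LF", -0.6), ("EC", -0.6), ("LC", 3.0))),
        ModuleSpec("culture", 150, None,
                   (("EF", 0.0), ("LF", 0.0), ("EC", 0.6), ("LC", 0.6))),
    )
    indicators: tuple[IndicatorSpec, ...] = (
        IndicatorSpec("field_up", (("fatty_acid_like", 15),
                                   ("oogenesis_like", 20),
                                   ("rna_metabolism_like", 5))),
        IndicatorSpec("culture_up", (("oogenesis_like", 15),
                                     ("rna_metabolism_like", 25))),
    )
    other_annotation_fraction: float = 0.5
    contamination: ContaminationSpec | None = ContaminationSpec(
        proportions=(
            ("EF_1", 0.32), ("EF_2", 0.20), ("EF_3", 0.15), ("EF_4", 0.25),
            ("LF_1", 0.30), ("LF_2", 0.10), ("LF_3", 0.22), ("LF_4", 0.28),
        )
    )
    seed: int = 42

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        tag_total = sum(n for _, n in self.tag_sizes)
        if tag_total > self.n_transcripts:
            raise ValueError("tag sizes exceed n_transcripts")
        tags = {t for t, _ in self.tag_sizes}
        for block in self.effect_blocks:
            if not np.isfinite(block.log2fc):
                raise ValueError("fold-changes must be finite")
            if block.tag not in tags:
                raise ValueError(f"effect block references unknown tag: {block.tag}")
        for spec in self.indicators:
            for tag, _ in spec.per_tag:
                if tag not in tags:
                    raise ValueError(f"indicator spec references unknown tag: {tag}")
        if self.contamination is not None:
            for _, p in self.contamination.proportions:
                if not 0.0 <= p <= 1.0:
                    raise ValueError("contamination proportions must lie in [0, 1]")
            if not 0.0 <= self.contamination.efficiency <= 1.0:
                raise ValueError("efficiency must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups for r in range(self.replicates)]


@dataclass
class SyntheticTruth:
    """Ground-truth labels for every planted structure."""

    de_labels: dict[str, dict[str, float]]  # contrast -> id -> signed log2fc
    module_labels: pd.Series  # module name per transcript, "0" = background
    indicator_ids: dict[str, frozenset]
    congener_truth: pd.Series | None = None
    contaminated_ids: frozenset = frozenset()
    tag_members: dict[str, frozenset] = dc_field(default_factory=dict)
    marker_counts: pd.DataFrame | None = None  # samples x species


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for g in config.groups:
        source = "field" if g in FIELD_GROUPS else "culture"
        timepoint = "early" if g.startswith("E") else "late"
        for r in range(config.replicates):
            rows.append({"sample_id": f"{g}_{r + 1}", "source": source,
                         "timepoint": timepoint, "group": g, "replicate": r + 1})
    return pd.DataFrame(rows).set_index("sample_id")


def _assign_tags(config: SimulationConfig, ids: list[str]) -> dict[str, list[str]]:
    out, start = {}, 0
    for tag, n in config.tag_sizes:
        out[tag] = ids[start:start + n]
        start += n
    out["__background__"] = ids[start:]
    return out


def generate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw (counts, catalog, samples, truth) for the configured design.

    Counts are NB with mean library_size x relative abundance x 2^(sum of
    planted log2 effects); identical config+seed gives identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_transcripts
    ids = [f"T{i:06d}" for i in range(n)]
    samples = _sample_table(config)
    sample_ids = list(samples.index)
    group_of = samples["group"]

    lengths = np.exp(
        rng.uniform(np.log(config.length_range[0]), np.log(config.length_range[1]), n)
    ).astype(int)
    baseline = rng.normal(config.baseline_logmean_mean, config.baseline_logmean_sd, n)
    phi = rng.gamma(config.dispersion_shape,
                    config.dispersion_mean / config.dispersion_shape, n)
    phi = np.clip(phi, 1e-4, None)

    tags = _assign_tags(config, ids)
    idx_of = {t: i for i, t in enumerate(ids)}

    # planted log2 effect per (transcript, group)
    delta = pd.DataFrame(0.0, index=ids, columns=config.groups)
    for block in config.effect_blocks:
        members = tags[block.tag]
        lo = int(round(block.span[0] * len(members)))
        hi = int(round(block.span[1] * len(members)))
        for g in block.groups:
            delta.loc[members[lo:hi], g] += block.log2fc

    # indicator genes override their tag's block effect with a large,
    # low-dispersion program effect
    indicator_ids: dict[str, frozenset] = {}
    used: set[str] = set()
    for spec in config.indicators:
        members: list[str] = []
        for tag, count in spec.per_tag:
            pool = [t for t in tags[tag] if t not in used]
            if count > len(pool):
                raise ValueError(f"not enough free transcripts in tag {tag}")
            chosen = list(rng.choice(pool, size=count, replace=False))
            members.extend(chosen)
            used.update(chosen)
        up_groups = FIELD_GROUPS if spec.direction == "field_up" else CULTURE_GROUPS
        for t in members:
            delta.loc[t, :] = 0.0
            for g in up_groups:
                delta.loc[t, g] = spec.log2fc
            phi[idx_of[t]] = min(phi[idx_of[t]], spec.dispersion)
        indicator_ids[spec.direction] = frozenset(members)

    # modules: shared latent factor, group level + per-sample jitter;
    # expected_effect tracks the realized per-gene group effects for truth
    module_labels = pd.Series("0", index=ids, name="module")
    module_offsets = np.zeros((n, len(sample_ids)))
    expected_effect = delta.copy()
    free_background = [t for t in tags["__background__"] if t not in used]
    for spec in config.modules:
        pool = (free_background if spec.tag is None
                else [t for t in tags[spec.tag] if t not in used])
        if spec.size > len(pool):
            raise ValueError(f"module {spec.name} larger than its pool")
        members = list(rng.choice(pool, size=spec.size, replace=False))
        used.update(members)
        if spec.tag is None:
            free_background = [t for t in free_background if t not in set(members)]
        module_labels.loc[members] = spec.name
        levels = dict(spec.levels)
        factor = np.array([
            levels.get(group_of[s], 0.0) + rng.normal(0.0, spec.jitter_sd)
            for s in sample_ids
        ])
        loadings = rng.normal(spec.loading_mean, spec.loading_sd, spec.size)
        if spec.mixed_loadings:
            # exactly half the loadings flipped: anti-correlated halves with
            # no net leakage into library composition
            signs = np.ones(spec.size)
            signs[: spec.size // 2] = -1.0
            loadings *= rng.permutation(signs)
        rows = [idx_of[t] for t in members]
        module_offsets[rows, :] += loadings[:, None] * factor[None, :]
        for g in config.groups:
            expected_effect.loc[members, g] += loadings * levels.get(g, 0.0)

    # boost indicator baselines so expected counts clear min_mean_count
    weight = 2.0 ** baseline
    lib_sizes = rng.lognormal(np.log(config.library_size_mean),
                              config.library_size_sigma, len(sample_ids))
    total_weight = weight.sum()
    for spec in config.indicators:
        floor_w = spec.min_mean_count * total_weight / config.library_size_mean
        for t in indicator_ids[spec.direction]:
            weight[idx_of[t]] = max(weight[idx_of[t]], floor_w)

    group_idx = np.array([list(config.groups).index(group_of[s]) for s in sample_ids])
    log2_shift = delta.to_numpy()[:, group_idx] + module_offsets
    rel = weight[:, None] * 2.0 ** log2_shift
    rel = rel / rel.sum(axis=0, keepdims=True)
    mu = rel * lib_sizes[None, :]

    r = 1.0 / phi
    lam = rng.gamma(shape=r[:, None], scale=(mu / r[:, None]))
    counts = rng.poisson(lam).astype(np.int64)
    counts = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"),
                          columns=sample_ids)

    truth = SyntheticTruth(
        de_labels=_true_de_labels(config, expected_effect),
        module_labels=module_labels,
        indicator_ids=indicator_ids,
        tag_members={t: frozenset(v) for t, v in tags.items() if t != "__background__"},
    )

    catalog = pd.DataFrame(
        {"length_bp": lengths, "annotation": [pd.NA] * n,
         "go_terms": [frozenset()] * n, "cross_map_flag": False},
        index=pd.Index(ids, name="transcript_id"),
    )

    if config.contamination is not None:
        counts, markers, update = inject_contamination(
            counts, catalog,
            pd.Series(dict(config.contamination.proportions), dtype=float),
            config.contamination.efficiency,
            rng=rng,
            prone_pool=free_background,
            spec=config.contamination,
        )
        truth.congener_truth = update["congener_truth"]
        truth.contaminated_ids = update["contaminated_ids"]
        catalog.loc[list(truth.contaminated_ids), "cross_map_flag"] = True
        truth.marker_counts = markers

    return counts, catalog, samples, truth


def _true_de_labels(
    config: SimulationConfig, total: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Expected log2 group differences from blocks, indicators and the
    realized module loadings (jitter excluded: it is noise, not signal)."""
    labels: dict[str, dict[str, float]] = {}
    pairs = [(a, b) for i, a in enumerate(config.groups)
             for b in config.groups[i + 1:]]
    global_set: dict[str, float] = {}
    for a, b in pairs:
        diff = total[a] - total[b]
        hits = diff[diff.abs() > 1e-9]
        labels[f"{a}v{b}"] = dict(hits)
        for t, v in hits.items():
            if t not in global_set or abs(v) > abs(global_set[t]):
                global_set[t] = v
    labels["global"] = global_set
    return labels


# ---------------------------------------------------------------------------
# Ontology generation


def generate_ontology(
    config: SimulationConfig | None = None,
    truth: SyntheticTruth | None = None,
    seed: int | None = None,
) -> tuple[OntologyGraph, dict[str, frozenset]]:
    """Toy is_a DAG plus transcript annotations realizing the configured tags.

    One root; per tag a named parent term with two child terms; each tagged
    transcript is annotated to one of the children, so the tag's
    descendant-closure filter contains exactly the configured number of
    transcripts.  A configurable fraction of background transcripts gets an
    unrelated annotation so the enrichment universe is not just the tags.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    if truth is None:
        ids = [f"T{i:06d}" for i in range(config.n_transcripts)]
        tags = _assign_tags(config, ids)
        tag_members = {t: frozenset(v) for t, v in tags.items() if t != "__background__"}
        background = tags["__background__"]
    else:
        tag_members = truth.tag_members
        all_tagged = frozenset().union(*tag_members.values()) if tag_members else frozenset()
        background = [t for t in truth.module_labels.index if t not in all_tagged]

    graph = nx.DiGraph()
    root_id, root_name = ROOT_TERM
    graph.add_node(root_id, name=root_name)
    other_id, other_name = OTHER_TERM
    graph.add_node(other_id, name=other_name)
    graph.add_edge(other_id, root_id)

    annotation: dict[str, frozenset] = {}
    for k, (tag, _) in enumerate(config.tag_sizes):
        parent_id, parent_name = TAG_TERMS.get(tag, (f"GO:90000{k:02d}", tag))
        graph.add_node(parent_id, name=parent_name)
        graph.add_edge(parent_id, root_id)
        children = []
        for c in range(2):
            child_id = f"GO:9{k + 1:02d}{c:04d}"
            graph.add_node(child_id, name=f"{parent_name} child {c + 1}")
            graph.add_edge(child_id, parent_id)
            children.append(child_id)
        members = sorted(tag_members.get(tag, frozenset()))
        for t in members:
            child = children[int(rng.integers(0, len(children)))]
            annotation[t] = annotation.get(t, frozenset()) | {child}

    for t in background:
        if rng.random() < config.other_annotation_fraction:
            annotation[t] = annotation.get(t, frozenset()) | {other_id}

    return OntologyGraph(graph), annotation


def tag_term(tag: str) -> str:
    """GO-style parent term id of a synthetic tag."""
    return TAG_TERMS[tag][0]


# ---------------------------------------------------------------------------
# Contamination


def inject_contamination(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    proportions: pd.Series,
    efficiency: float = 0.30,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    prone_pool: list[str] | None = None,
    spec: ContaminationSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Re-attribute a fraction of reads to a congener, library size preserved.

    For a sample with congener share p, round(p x efficiency x N) reads are
    moved onto a designated cross-map-prone transcript subset (multinomial
    over fixed weights); the remaining reads are thinned from the focal
    counts without replacement so the total stays exactly N.  Marker counts
    (mtCOI) reflect the true composition.  Returns (counts, markers,
    truth-update) where markers is samples x species.
    """
    spec = spec or ContaminationSpec(proportions=tuple(proportions.items()),
                                     efficiency=efficiency)
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if ((proportions < 0) | (proportions > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")

    ids = list(counts.index)
    pool = prone_pool if prone_pool is not None else ids
    n_prone = min(spec.n_prone, len(pool))
    prone = sorted(rng.choice(pool, size=n_prone, replace=False)) if n_prone else []
    prone_weights = rng.dirichlet(np.ones(len(prone))) if prone else np.array([])
    prone_rows = [ids.index(t) for t in prone]

    out = counts.copy()
    marker_rows = {}
    full = proportions.reindex(counts.columns).fillna(0.0)
    for sample in counts.columns:
        p = float(full[sample])
        marker_rows[sample] = rng.multinomial(
            spec.marker_total, [1.0 - p, p]
        )
        if p == 0.0 or not prone:
            continue
        col = counts[sample].to_numpy()
        total = int(col.sum())
        n_congener = int(round(p * efficiency * total))
        if n_congener == 0:
            continue
        kept = rng.multivariate_hypergeometric(col, total - n_congener,
                                               method="marginals")
        congener = rng.multinomial(n_congener, prone_weights)
        kept = kept.copy()
        kept[prone_rows] += congener
        out[sample] = kept
    markers = pd.DataFrame(
        marker_rows, index=[spec.focal_species, spec.congener_species]
    ).T
    update = {
        "congener_truth": full.rename("congener_proportion"),
        "contaminated_ids": frozenset(prone),
    }
    return out, markers, update


# ---------------------------------------------------------------------------
# Canned configurations for calibration studies


def null_config(n_transcripts: int = 2000, seed: int = 1) -> SimulationConfig:
    """No planted structure at all: for type-I-error calibration."""
    return SimulationConfig(
        n_transcripts=n_transcripts, tag_sizes=(), effect_blocks=(),
        modules=(), indicators=(), contamination=None, seed=seed,
    )


def planted_de_config(
    n_transcripts: int = 2000, frac: float = 0.1, log2fc: float = 1.5, seed: int = 1
) -> SimulationConfig:
    """A fraction of transcripts with |log2FC| >= log2fc between programs,
    half up and half down in field: for sensitivity/FDR calibration."""
    n_up = int(n_transcripts * frac / 2)
    return SimulationConfig(
        n_transcripts=n_transcripts,
        tag_sizes=(("planted_up", n_up), ("planted_down", n_up)),
        effect_blocks=(
            EffectBlock("planted_up", FIELD_GROUPS, log2fc),
            EffectBlock("planted_down", FIELD_GROUPS, -log2fc),
        ),
        modules=(), indicators=(), contamination=None, seed=seed,
    )


def module_recovery_config(seed: int = 1) -> SimulationConfig:
    """3 strong planted modules (120 genes each) plus 200 background genes
    on high, tight counts: for module-recovery checks."""
    levels = [
        (("EF", 1.8), ("LF", 1.8), ("EC", -1.8), ("LC", -1.8)),
        (("EF", -1.8), ("LF", 1.8), ("EC", 1.8), ("LC", -1.8)),
        (("EF", 1.8), ("LF", -1.8), ("EC", 1.8), ("LC", -1.8)),
    ]
    return SimulationConfig(
        n_transcripts=560,
        baseline_logmean_sd=0.6,
        dispersion_mean=0.05,
        tag_sizes=(), effect_blocks=(), indicators=(), contamination=None,
        modules=tuple(
            ModuleSpec(f"m{i + 1}", 120, None, lv, loading_mean=0.9,
                       loading_sd=0.05, jitter_sd=0.35)
            for i, lv in enumerate(levels)
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Dataset export


def write_dataset(
    outdir: str | Path,
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
    truth: SyntheticTruth,
    graph: OntologyGraph | None = None,
    annotation: dict[str, frozenset] | None = None,
) -> None:
    """Write the standard pipeline inputs: counts/catalog/samples TSV,
    ontology OBO, marker TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cat = catalog.copy()
    if annotation is not None:
        cat["go_terms"] = [annotation.get(t, frozenset()) for t in cat.index]
    expr_mod.write_counts(counts, outdir / "counts.tsv")
    expr_mod.write_catalog(cat, outdir / "catalog.tsv")
    expr_mod.write_samples(samples, outdir / "samples.tsv")
    if graph is not None:
        write_obo(graph, outdir / "ontology.obo")
    if truth.marker_counts is not None:
        truth.marker_counts.to_csv(outdir / "markers.tsv", sep="\t",
                                   index_label="sample_id")
    payload = {
        "de_labels": {c: dict(v) for c, v in truth.de_labels.items()},
        "module_labels": truth.module_labels.to_dict(),
        "indicator_ids": {k: sorted(v) for k, v in truth.indicator_ids.items()},
        "congener_truth": (truth.congener_truth.to_dict()
                           if truth.congener_truth is not None else None),
        "contaminated_ids": sorted(truth.contaminated_ids),
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
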
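"""Seeded synthetic-data generator for the whole pipeline.

Emulates, at desk scale, the inputs the network pipeline consumes:

- a multi-dataset expression compendium per condition with planted
  TF -> module regulation whose coupling changes between control and
  stress (bivariate-normal construction, so the population correlation of
  a module gene with its TF equals the coupling parameter exactly when
  noise_sd = 1);
- a toy rooted GO-style DAG with one term per planted module (annotated
  exactly to the module members), background terms, and deliberately
  redundant term pairs that the Jaccard pruning step must collapse;
- a two-group (wild-type vs transgenic) expression experiment with
  planted differentially expressed genes.

Every generator is a pure function of its configuration (which includes
the seed): the same config yields bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .compendium import (
    ExpressionCompendium,
    write_expression_tsv,
    write_sample_map_tsv,
)
from .exceptions import ConfigurationError


@dataclass
class ModuleSpec:
    """One planted regulatory module: a TF driving a set of member genes."""

    tf_index: int
    member_gene_indices: tuple[int, ...]
    coupling_control: float
    coupling_stress: float

    def __post_init__(self) -> None:
        self.member_gene_indices = tuple(self.member_gene_indices)
        for c in (self.coupling_control, self.coupling_stress):
            if not -1.0 <= c <= 1.0:
                raise ConfigurationError(f"coupling {c} outside [-1, 1]")


@dataclass
class DESpec:
    n_de_genes: int = 50
    effect_size: float = 3.0
    n_per_group: int = 10


@dataclass
class OntologySpec:
    n_terms: int = 40
    max_depth: int = 4
    planted_redundant_pairs: int = 3


@dataclass
class SyntheticConfig:
    """Configuration of all synthetic inputs; validated on construction."""

    n_genes: int = 600
    n_tfs: int = 30
    n_samples_control: int = 120
    n_samples_stress: int = 120
    n_datasets: int = 4
    module_specs: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 1.0
    de_spec: DESpec = field(default_factory=DESpec)
    ontology_spec: OntologySpec = field(default_factory=OntologySpec)
    seed: int = 17

    def __post_init__(self) -> None:
        self.module_specs = tuple(self.module_specs)
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_tfs > self.n_genes:
            raise ConfigurationError("n_tfs must not exceed n_genes")
        if self.n_datasets < 1:
            raise ConfigurationError("n_datasets must be >= 1")
        seen: set[int] = set()
        for mod in self.module_specs:
            if not 0 <= mod.tf_index < self.n_tfs:
                raise ConfigurationError(f"tf_index {mod.tf_index} out of range [0, n_tfs)")
            members = set(mod.member_gene_indices)
            if any(not 0 <= g < self.n_genes for g in members):
                raise ConfigurationError("module member index out of range [0, n_genes)")
            if mod.tf_index in members:
                raise ConfigurationError("module members must exclude their own TF index")
            if members & seen:
                raise ConfigurationError("module member sets must be disjoint")
            seen |= members

    # -- id vocabularies ----------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def tf_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_tfs)]


def default_config(seed: int = 17) -> SyntheticConfig:
    """The study configuration used throughout the test-bench.

    600 genes, 30 TFs, 120 samples per condition in 4 datasets, noise s.d. 1,
    and 5 planted modules of 20 genes at control coupling 0.8.  TF g0000
    drives two modules (the screening query processes; stress couplings 0 and
    -0.6) and TFs g0001-g0003 drive one module each (stress couplings -0.6,
    0, -0.6), planting both flips and attenuations.
    """
    stress_couplings = (0.0, -0.6, -0.6, 0.0, -0.6)
    tf_for_module = (0, 0, 1, 2, 3)
    modules = []
    for k in range(5):
        start = 100 + 20 * k
        modules.append(
            ModuleSpec(
                tf_index=tf_for_module[k],
                member_gene_indices=tuple(range(start, start + 20)),
                coupling_control=0.8,
                coupling_stress=stress_couplings[k],
            )
        )
    return SyntheticConfig(module_specs=tuple(modules), seed=seed)


MODULE_TERM = "SYN:M{k:03d}"
BACKGROUND_TERM = "SYN:B{k:03d}"
REDUNDANT_TERM = "SYN:R{k:03d}{w}"
ROOT_TERM = "SYN:ROOT"


@dataclass
class PlantedTruth:
    """Ground-truth labels for recovery testing."""

    regulated_pairs: dict[str, set[tuple[str, str]]]  # condition -> {(tf_id, gene_id)}
    process_truth: dict[str, tuple[str, float, float]]  # term -> (tf_id, sign_c, sign_s)
    de_genes: set[str]
    redundant_term_pairs: set[tuple[str, str]]  # (larger, smaller)


def _sample_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def _dataset_map(sample_ids: Sequence[str], n_datasets: int) -> pd.Series:
    return pd.Series(
        [f"D{i % n_datasets}" for i in range(len(sample_ids))], index=list(sample_ids)
    )


def _one_condition(
    config: SyntheticConfig, rng: np.random.Generator, condition: str, n_samples: int
) -> ExpressionCompendium:
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    # TFs are standard normal regardless of noise_sd
    values[: config.n_tfs] = rng.normal(0.0, 1.0, size=(config.n_tfs, n_samples))
    for mod in config.module_specs:
        coupling = mod.coupling_control if condition == "control" else mod.coupling_stress
        tf_row = values[mod.tf_index]
        for g in mod.member_gene_indices:
            eps = rng.normal(0.0, config.noise_sd, size=n_samples)
            values[g] = coupling * tf_row + np.sqrt(1.0 - coupling**2) * eps
    prefix = "c" if condition == "control" else "s"
    samples = _sample_ids(prefix, n_samples)
    data = pd.DataFrame(values, index=config.gene_ids(), columns=samples)
    return ExpressionCompendium(data, _dataset_map(samples, config.n_datasets), condition)


def generate_compendium(
    config: SyntheticConfig,
) -> tuple[ExpressionCompendium, ExpressionCompendium, PlantedTruth]:
    """Control and stress compendia with planted module regulation."""
    rng = np.random.default_rng([config.seed, 0])
    control = _one_condition(config, rng, "control", config.n_samples_control)
    stress = _one_condition(config, rng, "stress", config.n_samples_stress)
    genes = config.gene_ids()
    regulated: dict[str, set[tuple[str, str]]] = {"control": set(), "stress": set()}
    process_truth: dict[str, tuple[str, float, float]] = {}
    for k, mod in enumerate(config.module_specs):
        tf_id = genes[mod.tf_index]
        for cond, coupling in (
            ("control", mod.coupling_control),
            ("stress", mod.coupling_stress),
        ):
            if coupling != 0.0:
                regulated[cond] |= {(tf_id, genes[g]) for g in mod.member_gene_indices}
        process_truth[MODULE_TERM.format(k=k)] = (
            tf_id,
            float(np.sign(mod.coupling_control)),
            float(np.sign(mod.coupling_stress)),
        )
    truth = PlantedTruth(regulated, process_truth, set(), set())
    return control, stress, truth


def generate_go_dag(
    config: SyntheticConfig,
) -> tuple[nx.MultiDiGraph, pd.DataFrame, PlantedTruth]:
    """Toy rooted ontology DAG plus direct annotations.

    One term per planted module annotated exactly to its members; planted
    redundant pairs (B is_a A with B = A minus 2 genes, so after propagation
    |A| - |B| = 2 < 5 and Jaccard >= 0.9); remaining terms are background
    with random annotations, arranged in chains no deeper than max_depth.
    """
    spec = config.ontology_spec
    if spec.n_terms < 1 or spec.max_depth < 1:
        raise ConfigurationError("ontology_spec counts must be positive")
    if spec.planted_redundant_pairs > spec.n_terms // 2:
        raise ConfigurationError("planted redundant pairs cannot exceed half the terms")
    n_structural = 1 + len(config.module_specs) + 2 * spec.planted_redundant_pairs
    if spec.n_terms < n_structural:
        raise ConfigurationError(
            f"n_terms={spec.n_terms} too small for {n_structural} structural terms"
        )
    rng = np.random.default_rng([config.seed, 1])
    genes = np.array(config.gene_ids())
    module_members = {g for mod in config.module_specs for g in mod.member_gene_indices}
    background_pool = np.array(
        [g for i, g in enumerate(genes) if i not in module_members and i >= config.n_tfs]
    )

    graph = nx.MultiDiGraph()
    graph.add_node(ROOT_TERM, name="biological process root", namespace="biological_process")
    annotations: list[tuple[str, str]] = []

    if spec.n_terms == 1:
        return graph, pd.DataFrame(annotations, columns=["gene_id", "term_id"]), PlantedTruth(
            {"control": set(), "stress": set()}, {}, set(), set()
        )

    for k, mod in enumerate(config.module_specs):
        term = MODULE_TERM.format(k=k)
        graph.add_node(term, name=f"planted module {k} process", namespace="biological_process")
        graph.add_edge(term, ROOT_TERM, key="is_a")
        annotations.extend((genes[g], term) for g in mod.member_gene_indices)

    redundant_pairs: set[tuple[str, str]] = set()
    for k in range(spec.planted_redundant_pairs):
        big = REDUNDANT_TERM.format(k=k, w="A")
        small = REDUNDANT_TERM.format(k=k, w="B")
        pool_size = min(40, len(background_pool))
        chosen = rng.choice(background_pool, size=pool_size, replace=False)
        small_genes = chosen[:-2]
        graph.add_node(big, name=f"redundant process {k} (general)", namespace="biological_process")
        graph.add_node(small, name=f"redundant process {k} (specific)", namespace="biological_process")
        graph.add_edge(big, ROOT_TERM, key="is_a")
        graph.add_edge(small, big, key="is_a")
        annotations.extend((g, big) for g in chosen[-2:])
        annotations.extend((g, small) for g in small_genes)
        redundant_pairs.add((big, small))

    n_background = spec.n_terms - n_structural
    depth_of: dict[str, int] = {ROOT_TERM: 0}
    previous = ROOT_TERM
    for k in range(n_background):
        term = BACKGROUND_TERM.format(k=k)
        graph.add_node(term, name=f"background process {k}", namespace="biological_process")
        if depth_of[previous] + 1 < spec.max_depth:
            parent = previous
        else:
            parent = ROOT_TERM
        rel = "is_a" if k % 2 == 0 else "part_of"
        graph.add_edge(term, parent, key=rel)
        depth_of[term] = depth_of[parent] + 1
        previous = term
        size = int(rng.integers(6, 30))
        members = rng.choice(background_pool, size=min(size, len(background_pool)), replace=False)
        annotations.extend((g, term) for g in members)

    direct = pd.DataFrame(annotations, columns=["gene_id", "term_id"]).drop_duplicates()
    truth = PlantedTruth({"control": set(), "stress": set()}, {}, set(), redundant_pairs)
    return graph, direct, truth


def generate_two_group_experiment(
    config: SyntheticConfig,
) -> tuple[ExpressionCompendium, pd.Series, PlantedTruth]:
    """Wild-type vs transgenic two-group experiment with planted DE genes."""
    spec = config.de_spec
    if spec.n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2 (variance undefined below)")
    if spec.n_de_genes > config.n_genes:
        raise ConfigurationError("n_de_genes cannot exceed n_genes")
    rng = np.random.default_rng([config.seed, 2])
    n_samples = 2 * spec.n_per_group
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    genes = config.gene_ids()
    if spec.effect_size != 0.0 and spec.n_de_genes > 0:
        de_idx = rng.choice(config.n_genes, size=spec.n_de_genes, replace=False)
        values[de_idx, spec.n_per_group :] += spec.effect_size
        de_genes = {genes[i] for i in de_idx}
    else:
        de_genes = set()
    samples = _sample_ids("e", n_samples)
    labels = pd.Series(
        ["wild_type"] * spec.n_per_group + ["transgenic"] * spec.n_per_group, index=samples
    )
    data = pd.DataFrame(values, index=genes, columns=samples)
    comp = ExpressionCompendium(data, pd.Series("DE0", index=samples), "control")
    truth = PlantedTruth({"control": set(), "stress": set()}, {}, de_genes, set())
    return comp, labels, truth


# ----------------------------------------------------------------------
# Bundles and fixture writing
# ----------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """Everything the pipeline needs, generated from one configuration."""

    config: SyntheticConfig
    control: ExpressionCompendium
    stress: ExpressionCompendium
    ontology: nx.MultiDiGraph
    annotations: pd.DataFrame
    de_compendium: ExpressionCompendium
    de_groups: pd.Series
    truth: PlantedTruth

    @property
    def tf_ids(self) -> list[str]:
        return self.config.tf_ids()


def generate_all(config: SyntheticConfig) -> SyntheticBundle:
    """Generate every artifact and merge the planted truths."""
    control, stress, truth = generate_compendium(config)
    graph, annotations, go_truth = generate_go_dag(config)
    de_comp, de_groups, de_truth = generate_two_group_experiment(config)
    truth.redundant_term_pairs = go_truth.redundant_term_pairs
    truth.de_genes = de_truth.de_genes
    return SyntheticBundle(
        config, control, stress, graph, annotations, de_comp, de_groups, truth
    )


def write_obo(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Write the ontology as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(graph.nodes):
        data = graph.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        lines.append(f"namespace: {data.get('namespace', 'biological_process')}")
        for _, parent, key in sorted(graph.out_edges(term, keys=True)):
            if key == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {key} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(bundle: SyntheticBundle, directory: str | Path) -> pd.DataFrame:
    """Write all artifacts as plain-text files; returns the manifest.

    The manifest lists one row per written file with its SHA-256 checksum
    (so regenerating with a different seed changes the checksums).
    """
    out = Path(directory)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigurationError(f"cannot create output directory {out}: {exc}") from exc

    files: dict[str, Path] = {}

    def register(name: str) -> Path:
        files[name] = out / name
        return files[name]

    write_expression_tsv(bundle.control.data, register("expression_control.tsv"))
    write_sample_map_tsv(
        bundle.control.dataset_of_sample, "control", register("sample_map_control.tsv")
    )
    write_expression_tsv(bundle.stress.data, register("expression_stress.tsv"))
    write_sample_map_tsv(
        bundle.stress.dataset_of_sample, "stress", register("sample_map_stress.tsv")
    )
    register("tf_list.txt").write_text("\n".join(bundle.tf_ids) + "\n")
    write_obo(bundle.ontology, register("ontology.obo"))
    bundle.annotations.to_csv(register("annotations.tsv"), sep="\t", index=False)
    write_expression_tsv(bundle.de_compendium.data, register("expression_two_group.tsv"))
    bundle.de_groups.rename("group").to_frame().to_csv(
        register("groups_two_group.tsv"), sep="\t", index_label="sample_id"
    )

    truth = bundle.truth
    truth_payload = {
        "regulated_pairs": {c: sorted(map(list, p)) for c, p in truth.regulated_pairs.items()},
        "process_truth": {t: list(v) for t, v in truth.process_truth.items()},
        "de_genes": sorted(truth.de_genes),
        "redundant_term_pairs": sorted(map(list, truth.redundant_term_pairs)),
    }
    register("planted_truth.json").write_text(json.dumps(truth_payload, indent=1))

    manifest = pd.DataFrame(
        [(name, _sha256(path)) for name, path in sorted(files.items())],
        columns=["file", "sha256"],
    )
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    return manifest
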
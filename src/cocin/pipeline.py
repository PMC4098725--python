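"""End-to-end pipeline: build the interolog network, cluster it,
back-project clusters, and evaluate against the conserved-complex gold
standard — plus the two comparison arms (direct clustering of the raw
networks, and clustering of the conserved subnetworks).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io
from .clustering import ClusterSet, adjustcd_weights, cluster_graph
from .errors import ValidationError
from .evaluation import (
    ConservedBenchmark,
    EvaluationReport,
    build_conserved_benchmark,
    evaluate,
)
from .homology import OrthologMap
from .interolog import build_interolog_network, conserved_subnetwork, project_cluster
from .networks import ComplexCatalog, PPINetwork
from .synthetic import ScenarioParams, Scenario, generate_scenario

logger = logging.getLogger(__name__)

DEFAULT_ENGINE_PARAMS: dict[str, dict] = {
    "cmc": {"min_size": 4, "overlap_threshold": 0.5, "merge_threshold": 0.25},
    "mcl": {"inflation": 2.0, "expansion": 2, "self_loop_weight": 1.0,
            "prune_threshold": 1e-5, "max_iterations": 200,
            "tolerance": 1e-6, "min_size": 4},
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; serializable to YAML
    and written beside every run's outputs."""

    # inputs: either a synthetic scenario ...
    simulate: bool = True
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    # ... or paths to on-disk inputs
    ppi_a: str | None = None
    ppi_b: str | None = None
    orthologs: str | None = None
    complexes_a: str | None = None
    complexes_b: str | None = None
    species_a: str = "yeast"
    species_b: str = "human"
    catalog_dialect: str = "membership_rows"
    # preprocessing / construction
    score_edges_iterations: int = 0  # 0 = no iterative re-weighting
    include_shared_protein_edges: bool = True
    prune_isolated: bool = True
    # clustering
    engine: str = "mcl"
    engine_params: dict = field(default_factory=dict)
    # evaluation
    match_threshold: float = 0.50
    msj_threshold: float = 0.5
    min_complex_size: int = 4
    seed: int = 0
    out_dir: str | None = None

    def resolved_engine_params(self) -> dict:
        if self.engine not in DEFAULT_ENGINE_PARAMS:
            raise ValidationError(f"unknown clustering engine {self.engine!r}")
        params = dict(DEFAULT_ENGINE_PARAMS[self.engine])
        params.update(self.engine_params)
        return params

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario"] = self.scenario.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scenario" in d and not isinstance(d["scenario"], ScenarioParams):
            d["scenario"] = ScenarioParams.from_dict(d["scenario"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------

def load_inputs(config: RunConfig) -> Scenario:
    """Materialize the run's inputs: generate a synthetic scenario or
    read the configured files (benchmark rebuilt downstream)."""
    if config.simulate:
        params = config.scenario
        if params.seed != config.seed:
            params = ScenarioParams.from_dict({**params.to_dict(), "seed": config.seed})
        return generate_scenario(params)
    for name in ("ppi_a", "ppi_b", "orthologs", "complexes_a", "complexes_b"):
        value = getattr(config, name)
        if value is None:
            raise ValidationError(f"config.{name} is required when simulate=false")
        if not Path(value).exists():
            raise ValidationError(f"input file for {name} not found: {value}")
    net_a = io.read_ppi_edgelist(config.ppi_a, config.species_a, weighted=True)
    net_b = io.read_ppi_edgelist(config.ppi_b, config.species_b, weighted=True)
    omap = io.read_ortholog_groups(config.orthologs, config.species_a, config.species_b)
    catalog_a = io.read_complex_catalog(config.complexes_a, config.species_a, config.catalog_dialect)
    catalog_b = io.read_complex_catalog(config.complexes_b, config.species_b, config.catalog_dialect)
    empty = ConservedBenchmark([], config.msj_threshold, config.min_complex_size)
    return Scenario(net_a, net_b, omap, catalog_a, catalog_b, empty)


# ---------------------------------------------------------------------------
# Arms
# ---------------------------------------------------------------------------

def clusters_to_predicted_pairs(
    clusters: ClusterSet | list[frozenset],
) -> list[tuple[frozenset, frozenset]]:
    """Back-project interolog clusters to (side-a, side-b) protein-set
    pairs, one prediction per cluster."""
    node_sets = clusters.node_sets() if isinstance(clusters, ClusterSet) else clusters
    return [
        (project_cluster(c, "a"), project_cluster(c, "b")) for c in node_sets
    ]


def _prepared_networks(scenario: Scenario, config: RunConfig) -> tuple[PPINetwork, PPINetwork]:
    net_a, net_b = scenario.network_a, scenario.network_b
    if config.score_edges_iterations > 0:
        net_a = adjustcd_weights(net_a, config.score_edges_iterations)
        net_b = adjustcd_weights(net_b, config.score_edges_iterations)
    return net_a, net_b


def gold_standard(scenario: Scenario, config: RunConfig) -> ConservedBenchmark:
    return build_conserved_benchmark(
        scenario.catalog_a,
        scenario.catalog_b,
        scenario.orthologs,
        msj_threshold=config.msj_threshold,
        min_size=config.min_complex_size,
    )


def cocin_arm(
    scenario: Scenario, config: RunConfig, gold: ConservedBenchmark
) -> tuple[EvaluationReport, ClusterSet]:
    """The interolog pipeline: build GI, cluster, back-project, evaluate
    with paired matching."""
    net_a, net_b = _prepared_networks(scenario, config)
    interolog = build_interolog_network(
        net_a,
        net_b,
        scenario.orthologs,
        include_shared_protein_edges=config.include_shared_protein_edges,
        prune_isolated=config.prune_isolated,
    )
    clusters = cluster_graph(interolog, config.engine, **config.resolved_engine_params())
    predictions = clusters_to_predicted_pairs(clusters)
    report = evaluate(
        predictions, scenario.catalog_a, scenario.catalog_b, gold,
        t=config.match_threshold, paired=True,
    )
    return report, clusters


def direct_arm(
    scenario: Scenario, config: RunConfig, gold: ConservedBenchmark
) -> EvaluationReport:
    """Baseline: cluster each raw PPI network independently with the
    same engine and parameters; per-side matching."""
    net_a, net_b = _prepared_networks(scenario, config)
    params = config.resolved_engine_params()
    clusters_a = cluster_graph(net_a, config.engine, **params)
    clusters_b = cluster_graph(net_b, config.engine, **params)
    predictions = [(c, frozenset()) for c in clusters_a.node_sets()]
    predictions += [(frozenset(), c) for c in clusters_b.node_sets()]
    return evaluate(
        predictions, scenario.catalog_a, scenario.catalog_b, gold,
        t=config.match_threshold, paired=False,
    )


def conserved_subnetwork_arm(
    scenario: Scenario, config: RunConfig, gold: ConservedBenchmark
) -> EvaluationReport:
    """Comparison arm: cluster each species' conserved subnetwork (its
    interactions whose orthologous counterparts exist in the other
    species); per-side matching."""
    net_a, net_b = _prepared_networks(scenario, config)
    cs_a = conserved_subnetwork(net_a, net_b, scenario.orthologs)
    cs_b = conserved_subnetwork(net_b, net_a, scenario.orthologs)
    params = config.resolved_engine_params()
    clusters_a = cluster_graph(cs_a, config.engine, **params)
    clusters_b = cluster_graph(cs_b, config.engine, **params)
    predictions = [(c, frozenset()) for c in clusters_a.node_sets()]
    predictions += [(frozenset(), c) for c in clusters_b.node_sets()]
    return evaluate(
        predictions, scenario.catalog_a, scenario.catalog_b, gold,
        t=config.match_threshold, paired=False,
    )


# ---------------------------------------------------------------------------
# One-shot runs
# ---------------------------------------------------------------------------

def _write_report(report: EvaluationReport, out_dir: Path, stem: str) -> None:
    with open(out_dir / f"{stem}.json", "w", encoding="utf-8") as fh:
        json.dump(report.summary(), fh, indent=2)
        fh.write("\n")
    with open(out_dir / f"{stem}_matches.tsv", "w", encoding="utf-8") as fh:
        fh.write("prediction\tside\tbenchmark\tjaccard\n")
        for pid, side, cid, j in report.matched_predictions:
            fh.write(f"{pid}\t{side}\t{cid}\t{j!r}\n")


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Full interolog run; when ``config.out_dir`` is set, writes all
    intermediate artifacts, the report, and the resolved config."""
    scenario = load_inputs(config)
    gold = gold_standard(scenario, config)
    report, clusters = cocin_arm(scenario, config, gold)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_ppi_edgelist(scenario.network_a, out / "ppi_a.tsv")
        io.write_ppi_edgelist(scenario.network_b, out / "ppi_b.tsv")
        io.write_ortholog_groups(scenario.orthologs, out / "orthologs.txt")
        io.write_complex_catalog(scenario.catalog_a, out / "complexes_a.tsv")
        io.write_complex_catalog(scenario.catalog_b, out / "complexes_b.tsv")
        io.write_benchmark(gold, out / "gold_benchmark.tsv")
        net_a, net_b = _prepared_networks(scenario, config)
        interolog = build_interolog_network(
            net_a, net_b, scenario.orthologs,
            include_shared_protein_edges=config.include_shared_protein_edges,
            prune_isolated=config.prune_isolated,
        )
        io.write_interolog_network(interolog, out / "interolog_network.tsv")
        io.write_clusters(clusters, out / "clusters.tsv", interolog=True)
        pairs = clusters_to_predicted_pairs(clusters)
        pred_a = ComplexCatalog(scenario.network_a.species)
        pred_b = ComplexCatalog(scenario.network_b.species)
        for k, (sa, sb) in enumerate(pairs, start=1):
            pred_a.add(f"pred{k}", sa)
            pred_b.add(f"pred{k}", sb)
        io.write_complex_catalog(pred_a, out / "predicted_a.tsv")
        io.write_complex_catalog(pred_b, out / "predicted_b.tsv")
        _write_report(report, out, "report")
        config.to_yaml(out / "resolved_config.yaml")
    return report


BASELINE_COLUMNS = [
    "method", "n_predicted", "n_matched", "precision",
    "n_gold_conserved", "n_detected", "recall_conserved",
]


def run_baselines(config: RunConfig) -> list[dict]:
    """Run all three arms on the same inputs and return comparison rows
    mirroring the per-method layout of the evaluation tables."""
    scenario = load_inputs(config)
    gold = gold_standard(scenario, config)
    cocin_report, _ = cocin_arm(scenario, config, gold)
    direct_report = direct_arm(scenario, config, gold)
    conserved_report = conserved_subnetwork_arm(scenario, config, gold)
    rows = []
    for name, report in (
        ("COCIN", cocin_report),
        (f"direct-{config.engine}", direct_report),
        (f"conserved-subnetwork-{config.engine}", conserved_report),
    ):
        rows.append({
            "method": name,
            "n_predicted": report.n_predictions,
            "n_matched": report.n_matched,
            "precision": report.precision,
            "n_gold_conserved": report.n_gold,
            "n_detected": report.n_detected,
            "recall_conserved": report.recall_conserved,
        })
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "baselines.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(BASELINE_COLUMNS) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in BASELINE_COLUMNS) + "\n")
        config.to_yaml(out / "resolved_config.yaml")
    return rows
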
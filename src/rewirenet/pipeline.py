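"""End-to-end orchestration: inputs -> GGRs -> fit -> selection -> outputs.

Stages run in the fixed order (a) read inputs, (b) differential
expression parental-vs-resistant, (c) per-condition GGR construction,
(d) harmonization and the joint Bayesian p1 fit, (e) aberrant-pair
selection, (f) pathway enrichment and V-structure mining.  Every output
table is sorted deterministically and the run summary records the seed
and the thresholds actually realized, so a rerun with the same config is
bit-for-bit identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import aberrant, enrich, ggr, io, p1, vstructures

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults follow the study design)."""

    expression_path: str = ""
    samples_path: str = ""
    annotation_path: str | None = None
    cancer_genes_path: str = ""
    ppi_path: str = ""
    pathway_gmts: dict[str, str] = field(default_factory=dict)  # db -> path
    links_path: str = ""
    out_dir: str = "results"

    de_alpha: float = 0.05
    direct_fraction: float = 0.20
    path_alpha: float = 0.05
    odds_fraction: float = 0.20
    posterior_fraction: float = 0.50
    q_cutoff: float = 0.05
    n_iter: int = 15_000
    burn_in: int = 10_000
    shared_theta: bool = False
    diagnostic_window: int = 25
    log_scale_expression: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "direct_fraction", "path_alpha",
                     "odds_fraction", "posterior_fraction", "q_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    aberrant_pairs: pd.DataFrame
    enrichment: pd.DataFrame
    vstructures: pd.DataFrame
    dysregulation: pd.DataFrame
    architecture: pd.DataFrame
    diagnostic: pd.DataFrame
    ggr_r: ggr.GGRNetwork
    ggr_p: ggr.GGRNetwork
    posteriors: pd.DataFrame
    red: set
    green: set
    summary: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("read_inputs")
def _read_inputs(config: RunConfig):
    conditions, replicates = io.read_sample_sheet(config.samples_path)
    annotation = (
        io.read_probe_annotation(config.annotation_path)
        if config.annotation_path
        else None
    )
    expr = io.read_expression(
        config.expression_path, conditions, replicates, annotation
    )
    cgc = io.read_gene_list(config.cancer_genes_path)
    ppi_graph = nx.Graph()
    ppi_graph.add_edges_from(io.read_ppi(config.ppi_path))
    collections = {
        db: io.read_gene_sets(path) for db, path in config.pathway_gmts.items()
    }
    links = io.read_link_network(config.links_path)
    return expr, cgc, ppi_graph, collections, links


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the results bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, cgc, ppi_graph, collections, links = _read_inputs(config)

    parental = expr.subset_conditions(io.PARENTAL)
    resistant = expr.subset_conditions(io.RESISTANT)

    @_stage("differential_expression")
    def _de():
        return ggr.differential_expression(
            expr,
            expr.samples_for(io.PARENTAL),
            expr.samples_for(io.RESISTANT),
            config.de_alpha,
        )

    de_table = _de()
    de_genes = set(de_table.index[de_table["de"]])
    log.info("%d DE genes at Bonferroni alpha %.3g", len(de_genes),
             config.de_alpha)

    @_stage("build_ggr")
    def _build(cond_expr, label):
        return ggr.build_ggr(
            de_genes, cgc, cond_expr, ppi_graph, label,
            config.direct_fraction, config.path_alpha,
        )

    ggr_r = _build(resistant, "R")
    ggr_p = _build(parental, "P")
    for net in (ggr_r, ggr_p):
        net.to_frame().to_csv(out / f"ggr_{net.condition}.tsv", sep="\t",
                              index=False)
        _write_nodes(out / f"ggr_{net.condition}_nodes.tsv", net)

    @_stage("harmonize")
    def _harm():
        return ggr.harmonize_conditions(ggr_r, ggr_p)

    final_genes, _restricted, dyads = _harm()
    dyads.to_frame().to_csv(out / "dyads.tsv", sep="\t", index=False)
    log.info("%d final seed genes, %d dyads", len(final_genes), len(dyads))

    @_stage("p1_fit")
    def _fit():
        cfg = p1.MCMCConfig(
            n_iter=config.n_iter, burn_in=config.burn_in, seed=config.seed,
            shared_theta=config.shared_theta,
        )
        return p1.fit(dyads, p1.PriorSpec(), cfg)

    fit_result = _fit()
    posteriors = p1.posterior_edge_probabilities(fit_result)
    posteriors.to_csv(out / "edge_posteriors.tsv", sep="\t", index=False)

    @_stage("select_aberrant")
    def _select():
        table, maxima = aberrant.normalize_posteriors(posteriors)
        table = aberrant.compute_odds(table)
        red, green, thresholds = aberrant.select_aberrant(
            table, config.odds_fraction, config.posterior_fraction
        )
        return table, maxima, red, green, thresholds

    table, maxima, red, green, thresholds = _select()
    pairs_df = aberrant.aberrant_table(table, red, green)
    pairs_df.to_csv(out / "aberrant_pairs.tsv", sep="\t", index=False)

    @_stage("diagnostic")
    def _diag():
        corr_r = ggr.CorrelationTable(resistant.values)
        corr_p = ggr.CorrelationTable(parental.values)
        pcc_r = {p: corr_r.pcc(*p) for p in red | green}
        pcc_p = {p: corr_p.pcc(*p) for p in red | green}
        return aberrant.posterior_pcc_diagnostic(
            pairs_df, pcc_r, pcc_p, config.diagnostic_window
        )

    diagnostic = _diag()
    diagnostic.to_csv(out / "posterior_pcc_diagnostic.tsv", sep="\t",
                      index=False)

    @_stage("enrichment")
    def _enrich():
        return enrich.enrich_pathways(collections, links, red, green,
                                      config.q_cutoff)

    enrichment = _enrich()
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    @_stage("vstructures")
    def _vs():
        structures = vstructures.enumerate_vstructures(red, green)
        vs_df = vstructures.vstructure_table(structures, collections, links)
        incident = sorted({g for p in red | green for g in p})
        dys = vstructures.dysregulation_table(
            expr, incident, log_scale=config.log_scale_expression
        )
        calls = dict(zip(dys["gene"], dys["dysregulated"]))
        arch = vstructures.architecture_summary(red, green, calls)
        return vs_df, dys, arch

    vs_df, dys, arch = _vs()
    vs_df.to_csv(out / "vstructures.tsv", sep="\t", index=False)
    dys.to_csv(out / "dysregulation.tsv", sep="\t", index=False)
    arch.to_csv(out / "architecture_summary.tsv", sep="\t", index=False)

    summary = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_de_genes": int(len(de_genes)),
        "n_final_seed_genes": len(final_genes),
        "n_dyads": len(dyads),
        "direct_threshold_R": ggr_r.direct_threshold,
        "direct_threshold_P": ggr_p.direct_threshold,
        "posterior_maxima": maxima,
        "selection_thresholds": thresholds.to_dict(),
        "n_red": len(red),
        "n_green": len(green),
        "n_vstructures": int(vs_df["crossing_gene"].size // max(len(collections), 1))
        if len(vs_df) else 0,
        "fit": p1.fit_summary(fit_result),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True) + "\n")
    return PipelineResult(
        pairs_df, enrichment, vs_df, dys, arch, diagnostic,
        ggr_r, ggr_p, posteriors, red, green, summary,
    )


def _write_nodes(path: Path, net: ggr.GGRNetwork) -> None:
    rows = [
        (
            g,
            int(g in net.seed.de_genes),
            int(g in net.seed.cgc_genes),
            int(g in net.seed.linker_genes),
            net.condition,
        )
        for g in sorted(net.nodes)
    ]
    pd.DataFrame(
        rows, columns=["gene", "de", "cgc", "linker", "condition"]
    ).to_csv(path, sep="\t", index=False)
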
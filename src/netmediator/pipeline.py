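"""End-to-end orchestration of the central-gene analysis.

``central_gene_analysis`` runs the per-sample chain (node weights ->
weighted path graph -> candidate paths -> permutation null -> TopNet ->
ripple top-k) for every case sample and aggregates by frequency.
``run_all`` wires every stage behind a validated config and writes the
output tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netmediator import central_genes as cg
from netmediator import diffexp, enrichment, hubs_drugs, model_eval, single_cell
from netmediator import node_weights as nw
from netmediator import pathext_core as px
from netmediator.io_formats import (
    ExpressionMatrix,
    InteractionNetwork,
    read_expression,
    read_gmt,
    read_network,
)

logger = logging.getLogger("netmediator")

__all__ = ["PipelineConfig", "central_gene_analysis", "run_all"]


@dataclass
class PipelineConfig:
    """Validated parameters for ``run_all``; unknown keys are rejected."""

    expr: str = ""
    groups: str = ""
    network: str = ""
    gmt: str | None = None
    reference_lists: dict[str, str] = field(default_factory=dict)
    drugs: str | None = None
    sc_matrix: str | None = None
    sc_labels: str | None = None
    out: str = "netmediator_out"

    assume_log: bool = True
    pseudocount: float = 1.0
    min_conf: float = 0.0
    deg_method: str = "moderated"
    span: float = nw.DEFAULT_SPAN
    eps: float = nw.DEFAULT_EPS
    mode: str = "activated"
    terminal_fraction: float = 0.05
    n_perm: int = 200
    alpha: float = 0.05
    k: int = 100
    k_final: int = 100
    fdr_max: float = 0.05
    background: int = 20000
    min_size: int = 10
    max_size: int = 500
    folds: int = 5
    n_boot: int = 1000
    model: str = "rf"
    top_hubs: int = 10
    hub_min_conf: float = 0.7
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sample_topnet(
    expr: ExpressionMatrix,
    network: InteractionNetwork,
    sample: str,
    mode: str = "activated",
    span: float = nw.DEFAULT_SPAN,
    eps: float = nw.DEFAULT_EPS,
    terminal_fraction: float = 0.05,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> px.TopNet:
    """TopNet for one case sample."""
    weights = nw.sample_node_weights(expr, sample, mode=mode, span=span, eps=eps)
    graph = px.build_path_graph(network, weights, eps=eps)
    paths = px.candidate_paths(graph, terminal_fraction=terminal_fraction)
    pvals = px.permutation_significance(graph, paths, n_perm=n_perm, seed=seed)
    return px.build_topnet(paths, pvals, alpha=alpha)


def central_gene_analysis(
    expr: ExpressionMatrix,
    network: InteractionNetwork,
    mode: str = "activated",
    span: float = nw.DEFAULT_SPAN,
    eps: float = nw.DEFAULT_EPS,
    terminal_fraction: float = 0.05,
    n_perm: int = 200,
    alpha: float = 0.05,
    k: int = 100,
    k_final: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Per-sample TopNets for every case sample, aggregated by frequency.

    Returns (central gene table, per-sample top-k centrality series). The
    per-sample permutation seed is derived deterministically from ``seed``
    and the sample's position.
    """
    per_sample: dict[str, pd.Series] = {}
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=len(expr.case_samples))
    for s_i, sample in enumerate(expr.case_samples):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            topnet = sample_topnet(
                expr,
                network,
                sample,
                mode=mode,
                span=span,
                eps=eps,
                terminal_fraction=terminal_fraction,
                n_perm=n_perm,
                alpha=alpha,
                seed=int(sample_seeds[s_i]),
            )
        per_sample[sample] = cg.top_k_per_sample(topnet, k=k)
        logger.info("sample %s: TopNet %d nodes", sample, len(topnet.nodes))
    table = cg.frequency_rank(per_sample, k_final=k_final)
    return table, per_sample


def _write_table(df: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def run_all(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Outputs are pure functions of (inputs, config, seed); re-running with
    the same config is bit-identical.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    import yaml

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    note = f"seed={config.seed} n_perm={config.n_perm} alpha={config.alpha} k={config.k}"

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("ingest")
        groups = pd.read_csv(config.groups, sep="\t", index_col=0).iloc[:, 0].to_dict()
        expr = read_expression(
            config.expr, groups, pseudocount=config.pseudocount, assume_log=config.assume_log
        )
    except Exception as exc:  # noqa: BLE001
        logger.removeHandler(handler)
        raise RuntimeError(f"stage ingest failed: {exc}") from exc

    try:
        stage("deg")
        deg_table = diffexp.differential_expression(expr, method=config.deg_method)
        _write_table(deg_table, out / "degs.tsv", note)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top_degs = diffexp.select_top_degs(deg_table, k=config.k_final, fdr_max=config.fdr_max)
        (out / "top_degs.txt").write_text("\n".join(top_degs) + "\n")
    except Exception as exc:  # noqa: BLE001
        logger.removeHandler(handler)
        raise RuntimeError(f"stage deg failed: {exc}") from exc

    try:
        stage("pathext")
        network = read_network(config.network, min_confidence=config.min_conf)
        central, per_sample = central_gene_analysis(
            expr,
            network,
            mode=config.mode,
            span=config.span,
            eps=config.eps,
            terminal_fraction=config.terminal_fraction,
            n_perm=config.n_perm,
            alpha=config.alpha,
            k=config.k,
            k_final=config.k_final,
            seed=config.seed,
        )
        n_sig = central.attrs["n_significant_samples"]
        _write_table(
            central,
            out / "central_genes.tsv",
            note + f" significant_samples={n_sig}/{len(expr.case_samples)}",
        )
    except Exception as exc:  # noqa: BLE001
        logger.removeHandler(handler)
        raise RuntimeError(f"stage pathext failed: {exc}") from exc

    central_list = central.index.tolist()
    common = sorted(set(central_list) & set(top_degs))
    (out / "central_vs_deg_common.txt").write_text("\n".join(common) + "\n")

    if config.gmt:
        try:
            stage("enrich")
            collection = read_gmt(config.gmt)
            background = list(expr.genes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ora = enrichment.hypergeom_ora(
                    central_list,
                    collection,
                    background,
                    min_size=config.min_size,
                    max_size=config.max_size,
                )
            _write_table(enrichment.results_frame(ora), out / "enrichment.tsv", note)
        except Exception as exc:  # noqa: BLE001
            logger.removeHandler(handler)
            raise RuntimeError(f"stage enrich failed: {exc}") from exc

    if config.reference_lists:
        try:
            stage("overlap")
            results = []
            for name, path in sorted(config.reference_lists.items()):
                ref = [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]
                results.append(
                    enrichment.fisher_overlap(
                        central_list, ref, background_size=config.background, name=name
                    )
                )
            _write_table(enrichment.results_frame(results), out / "overlap.tsv", note)
        except Exception as exc:  # noqa: BLE001
            logger.removeHandler(handler)
            raise RuntimeError(f"stage overlap failed: {exc}") from exc

    if config.sc_matrix and config.sc_labels:
        try:
            stage("sc-overlay")
            matrix = pd.read_csv(config.sc_matrix, sep="\t", index_col=0)
            labels = pd.read_csv(config.sc_labels, sep="\t", index_col=0).iloc[:, 0]
            means, _, anova = single_cell.celltype_stats(matrix, labels)
            z = single_cell.zscore_across_types(means)
            overlay = single_cell.obs_exp_fraction(central_list, z)
            _write_table(overlay, out / "sc_overlay.tsv", note)
            _write_table(anova, out / "sc_anova.tsv", note)
        except Exception as exc:  # noqa: BLE001
            logger.removeHandler(handler)
            raise RuntimeError(f"stage sc-overlay failed: {exc}") from exc

    try:
        stage("classify")
        panel = [g for g in central_list if g in set(expr.genes)]
        cv = model_eval.cross_validate(
            expr, panel, config.model, folds=config.folds, seed=config.seed
        )
        ci = model_eval.bootstrap_ci(
            cv["scores"].to_numpy(),
            cv["labels"].to_numpy(),
            n_boot=config.n_boot,
            seed=config.seed,
        )
        report = pd.DataFrame(
            {
                "model": [config.model],
                "auroc": [cv["auroc"]],
                "auprc": [cv["auprc"]],
                "f1": [cv["f1"]],
                "auroc_ci_lo": [ci[0]],
                "auroc_ci_hi": [ci[1]],
            }
        ).set_index("model")
        _write_table(report, out / "eval.tsv", note)
    except Exception as exc:  # noqa: BLE001
        logger.removeHandler(handler)
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    try:
        stage("hubs")
        hubs = hubs_drugs.degree_hubs(
            central_list,
            network,
            min_confidence=config.hub_min_conf,
            top_n=config.top_hubs,
        )
        if config.drugs:
            drug_table = hubs_drugs.read_drug_table(config.drugs)
            hubs = hubs_drugs.map_drug_targets(hubs, drug_table)
        _write_table(hubs, out / "hubs.tsv", note)
    except ValueError as exc:
        logger.warning("stage hubs skipped: %s", exc)
    except Exception as exc:  # noqa: BLE001
        logger.removeHandler(handler)
        raise RuntimeError(f"stage hubs failed: {exc}") from exc

    logger.info("done")
    logger.removeHandler(handler)
    handler.close()
    return out
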
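"""End-to-end orchestration: filter -> build -> merge -> score -> key network
-> CDR -> enrichment comparison.

The pipeline is configured from a YAML mapping (unknown keys rejected), runs
each stage in order, writes every artifact plus a manifest of input hashes
and resolved parameters, and is byte-for-byte reproducible on unchanged
inputs: no timestamps, sorted JSON keys, deterministic iteration order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import io as kio
from .admet import select_active_components
from .cdr import rank_cdr, select_kfc
from .enrichment import effective_terms, method_coverage, read_gmt
from .importance import IMPORTANCE_METHODS, extract_key_network, score_nodes
from .network import build_ct_network, layer_degree_stats, merge_ctp
from .synthetic import recovery_metrics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``truth`` optionally points at a ground-truth key-component list (one id
    per line, as written by the synthetic generator) to report recovery
    metrics; ``gmt`` enables the enrichment comparison stage.
    """

    components: str
    ct_edges: str
    ppi: str
    disease_genes: str
    outdir: str
    gmt: Optional[str] = None
    truth: Optional[str] = None
    ob_threshold: float = 30.0
    combine: str = "all-rules"
    method: str = "novel"
    alpha: float = 0.5
    max_depth: int = 3
    cdr_threshold: float = 0.90
    universe_mode: str = "adjacent"
    static_ranking: bool = False
    enrich_alpha: float = 0.05
    enrich_adjusted: bool = False
    compare_methods: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        missing = {k for k in ("components", "ct_edges", "ppi", "disease_genes", "outdir")} - set(raw)
        if missing:
            raise ValueError(f"missing required config key(s): {sorted(missing)}")
        cfg = cls(**raw)
        if cfg.method not in IMPORTANCE_METHODS:
            raise ValueError(f"unknown importance method {cfg.method!r}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Optional[str], what: str) -> Optional[Path]:
    if path is None:
        return None
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the machine-readable report (also written).

    Any stage failure propagates with the stage name prepended.
    """
    inputs = {
        "components": _require(config.components, "component table"),
        "ct_edges": _require(config.ct_edges, "ct edge list"),
        "ppi": _require(config.ppi, "ppi edge list"),
        "disease_genes": _require(config.disease_genes, "pathogenic gene table"),
        "gmt": _require(config.gmt, "gene set (GMT)"),
        "truth": _require(config.truth, "ground truth"),
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("filter-admet")
        records = kio.read_component_table(inputs["components"])
        verdicts = select_active_components(records, config.ob_threshold, config.combine)
        active_ids = {v.component_id for v in verdicts if v.active}
        with (outdir / "admet_verdicts.tsv").open("w") as fh:
            fh.write("component_id\tlipinski\tob\tgi\tvalidated\tactive\n")
            fmt = lambda v: "-" if v is None else str(v).lower()
            for v in verdicts:
                fh.write(
                    f"{v.component_id}\t{fmt(v.lipinski_pass)}\t{fmt(v.ob_pass)}"
                    f"\t{fmt(v.gi_pass)}\t{fmt(v.validated)}\t{fmt(v.active)}\n"
                )
        report["stages"][name] = {"n_components": len(records), "n_active": len(active_ids)}

        name = stage("build-ct")
        all_edges = kio.read_ct_edges(inputs["ct_edges"])
        edges = [(c, t) for c, t in all_edges if c in active_ids]
        if len(edges) < len(all_edges):
            logger.info(
                "build-ct: %d edge(s) of inactive components dropped", len(all_edges) - len(edges)
            )
        active_records = [r for r in records if r.component_id in active_ids]
        ct = build_ct_network(active_records, edges)
        stats = layer_degree_stats(ct)
        report["stages"][name] = {
            "n_nodes": stats.n_nodes,
            "n_edges": stats.n_edges,
            "mean_component_degree": stats.per_layer["component"].mean_degree,
            "mean_target_degree": stats.per_layer["target"].mean_degree,
        }

        name = stage("merge-ctp")
        ppi_edges = kio.read_ppi_edges(inputs["ppi"])
        pathogenic = kio.read_pathogenic_table(inputs["disease_genes"])
        ctp = merge_ctp(ct, ppi_edges, pathogenic)
        kio.write_network(ctp, outdir / "ctp.graphml")
        report["stages"][name] = {"n_nodes": ctp.n_nodes(), "n_edges": ctp.n_edges()}

        name = stage("score")
        scores = score_nodes(ctp, config.method, config.alpha, config.max_depth)
        with (outdir / "scores.tsv").open("w") as fh:
            fh.write("node\tscore\n")
            for n in sorted(scores):
                fh.write(f"{n}\t{scores[n]!r}\n")
        result = extract_key_network(ctp, scores, config.method)
        kio.write_network(result.key_network, outdir / "key_network.graphml")
        report["stages"][name] = {
            "method": config.method,
            "median": result.median,
            "n_key_nodes": len(result.key_nodes),
            "n_key_edges": result.key_network.n_edges(),
        }

        name = stage("cdr")
        ranking = rank_cdr(result.key_network, config.universe_mode, config.static_ranking)
        kfc = select_kfc(ranking, config.cdr_threshold)
        with (outdir / "cdr.tsv").open("w") as fh:
            fh.write("rank\tcomponent_id\tcdr\tcumulative\n")
            for i, e in enumerate(ranking.entries, start=1):
                fh.write(f"{i}\t{e.component_id}\t{e.marginal!r}\t{e.cumulative!r}\n")
        (outdir / "kfc.txt").write_text("".join(c + "\n" for c in kfc))
        report["stages"][name] = {
            "universe_size": len(ranking.coverage_universe),
            "n_kfc": len(kfc),
            "kfc_coverage": ranking.cumulative_at(len(kfc)),
            "threshold": config.cdr_threshold,
        }

        if inputs["truth"] is not None:
            name = stage("recovery")
            truth = {
                line.strip() for line in inputs["truth"].read_text().splitlines() if line.strip()
            }
            if truth:
                k = min(len(kfc), len(ranking.entries)) or 1
                metrics = recovery_metrics(ranking, truth, min(k, len(ranking.entries)))
                report["stages"][name] = {"k": k, **metrics}
            else:
                report["stages"][name] = {"note": "empty truth set; recovery undefined"}

        if inputs["gmt"] is not None:
            name = stage("enrichment")
            gene_sets = read_gmt(inputs["gmt"])
            target_genes = ct.nodes_in_layer("target")
            pathogenic_genes = {g.symbol.upper() for g in pathogenic}
            eff = effective_terms(
                target_genes,
                pathogenic_genes,
                gene_sets,
                alpha=config.enrich_alpha,
                adjusted=config.enrich_adjusted,
            )
            entry: dict = {"n_effective_terms": len(eff)}
            if eff and config.compare_methods:
                results = {config.method: result}
                for m in IMPORTANCE_METHODS:
                    if m == config.method:
                        continue
                    s = score_nodes(ctp, m, config.alpha, config.max_depth)
                    results[m] = extract_key_network(ctp, s, m)
                cov = method_coverage(
                    results,
                    eff,
                    gene_sets,
                    alpha=config.enrich_alpha,
                    adjusted=config.enrich_adjusted,
                )
                with (outdir / "method_coverage.tsv").open("w") as fh:
                    fh.write("method\teffective_term_coverage\n")
                    for m in IMPORTANCE_METHODS:
                        fh.write(f"{m}\t{cov[m]!r}\n")
                entry["coverage"] = {m: cov[m] for m in IMPORTANCE_METHODS}
            report["stages"][name] = entry
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    manifest = {
        "inputs": {
            k: {"path": str(p), "sha256": _sha256(p)}
            for k, p in inputs.items()
            if p is not None
        },
        "config": asdict(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    (outdir / "config.resolved.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True)
    )
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
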
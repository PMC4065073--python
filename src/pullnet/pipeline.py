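"""End-to-end orchestration: config, staged analysis, report and outputs.

The full analysis reproduces the standard network workup of a pull-down
screen: merge literature interaction resources into one background
network; induce the hit-list subnetwork; test its interaction density
against a uniform sampling null; compare degree distributions to rule
out hub over-representation; detect communities by greedy modularity;
annotate communities and the whole list by Fisher-exact enrichment; and
look up disease-gene memberships. Every stage writes its outputs under
one run directory (TSV/JSON) with a manifest carrying input digests,
parameters and seeds, so each number in the report is recomputable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import community as community_mod
from . import density as density_mod
from . import enrichment as enrichment_mod
from . import io as io_mod

logger = logging.getLogger("pullnet")

__all__ = ["AnalysisConfig", "AnalysisReport", "StageError", "run_full_analysis"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """All inputs and parameters of one analysis run.

    ``edge_lists`` maps each background resource file to its dialect
    (``tsv2col``/``sif``). ``null_set_size_policy`` chooses whether the
    sampling null uses the matched hit count (``matched``, default: only
    matched nodes can contribute edges) or the full hit-list size
    (``total``).
    """

    edge_lists: dict[str, str]
    hit_list: str
    out_dir: str
    second_hit_list: str | None = None
    ortholog_map: str | None = None
    gmt_libraries: list[str] = field(default_factory=list)
    disease_library: str | None = None
    n_samples: int = 100_000
    seed: int = 0
    universe: str | int = "library"
    null_set_size_policy: str = "matched"
    min_cluster_size: int = 3
    bh_alpha: float = 0.05
    overlap_universe_size: int = enrichment_mod.DEFAULT_OVERLAP_UNIVERSE
    write_heatmap: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for path in self.input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.null_set_size_policy not in ("matched", "total"):
            raise ValueError("null_set_size_policy must be 'matched' or 'total'")
        if not (0 < self.bh_alpha < 1):
            raise ValueError("bh_alpha must be in (0, 1)")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    def input_paths(self) -> list[str]:
        paths = list(self.edge_lists) + [self.hit_list]
        for p in (self.second_hit_list, self.ortholog_map, self.disease_library):
            if p:
                paths.append(p)
        if self.universe != "library":
            paths.append(str(self.universe))
        paths.extend(self.gmt_libraries)
        return paths


@dataclass
class AnalysisReport:
    """Everything the run computed, plus the provenance needed to redo it."""

    config: dict[str, Any]
    input_digests: dict[str, str]
    background: dict[str, int]
    hit_matching: dict[str, Any]
    induced: dict[str, int]
    permutation: dict[str, Any] | None = None
    degree_comparison: dict[str, Any] | None = None
    communities: dict[str, Any] | None = None
    list_enrichment: dict[str, list[dict]] = field(default_factory=dict)
    cluster_top_terms: dict[str, dict[str, dict]] = field(default_factory=dict)
    disease_table: dict[str, list[str]] = field(default_factory=dict)
    overlap: dict[str, Any] | None = None
    warnings_issued: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _enrichment_frame(results: list[enrichment_mod.EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "term": r.term,
                "k": t.k,
                "K": t.K,
                "s": t.s,
                "N": t.N,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "p_adj": r.p_adj,
                "overlap": ";".join(sorted(r.overlap_symbols)),
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "k", "K", "s", "N", "odds_ratio", "p", "p_adj", "overlap"]
    )


def _result_dict(r: enrichment_mod.EnrichmentResult) -> dict:
    return {
        "term": r.term,
        "k": r.table.k,
        "K": r.table.K,
        "s": r.table.s,
        "N": r.table.N,
        "odds_ratio": r.odds_ratio,
        "p": r.p,
        "p_adj": r.p_adj,
        "overlap": sorted(r.overlap_symbols),
    }


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run every stage in order, writing outputs under ``config.out_dir``.

    A failure in any stage raises :class:`StageError` naming the stage;
    outputs written before the failure are left on disk and the manifest
    is flagged incomplete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    defaults = AnalysisConfig(edge_lists={}, hit_list="", out_dir="")
    for name in config.__dataclass_fields__:
        value = getattr(config, name)
        provenance = "default" if value == getattr(defaults, name, None) else "override"
        logger.info("param %s = %r (%s)", name, value, provenance)

    manifest: dict[str, Any] = {
        "config": asdict(config),
        "input_digests": {p: _digest(p) for p in config.input_paths()},
        "complete": False,
        "stages_done": [],
    }

    def save_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    caught: list[str] = []
    stage = "load_background"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            nets = [
                io_mod.read_edge_list(path, dialect=dialect, source_label=Path(path).name)
                for path, dialect in config.edge_lists.items()
            ]
            background = io_mod.merge_networks(nets)
            caught.extend(str(w.message) for w in wrec)
        logger.info("background: %d nodes, %d edges", background.n, background.m)
        manifest["stages_done"].append(stage)

        stage = "load_hits"
        hits = io_mod.read_gene_list(config.hit_list)
        matched = hits.as_set() & background.nodes
        hit_matching = {
            "n_hits_total": len(hits),
            "n_hits_in_network": len(matched),
            "unmatched": sorted(hits.as_set() - matched),
        }
        if not matched:
            msg = "PROMINENT WARNING: no hit-list symbol matches the background network"
            logger.warning(msg)
            caught.append(msg)
        manifest["stages_done"].append(stage)

        report = AnalysisReport(
            config=asdict(config),
            input_digests=manifest["input_digests"],
            background={"nodes": background.n, "edges": background.m},
            hit_matching=hit_matching,
            induced={"nodes": 0, "edges": 0},
        )

        stage = "induce"
        sub = None
        if matched:
            sub = density_mod.induce(background, hits)
            report.induced = {"nodes": sub.network.n, "edges": sub.m}
            io_mod.write_edge_list(sub.network, out / "induced_subnetwork.tsv")
        manifest["stages_done"].append(stage)

        stage = "permutation_density"
        if matched:
            set_size = (
                len(matched) if config.null_set_size_policy == "matched" else len(hits)
            )
            set_size = min(set_size, background.n)
            null = density_mod.permutation_density_test(
                background,
                set_size=set_size,
                observed=sub.m,
                n_samples=config.n_samples,
                seed=config.seed,
            )
            report.permutation = null.summary()
            np.savetxt(out / "null_counts.tsv", null.null_counts, fmt="%d")
            logger.info(
                "density null: observed=%d mean=%.2f p=%.3g",
                sub.m,
                null.null_counts.mean(),
                null.p_empirical,
            )
        manifest["stages_done"].append(stage)

        stage = "degree_comparison"
        if matched and sub.network.n >= 1:
            cmp = density_mod.compare_degree_distributions(
                density_mod.degree_distribution(sub.network),
                density_mod.degree_distribution(background),
            )
            report.degree_comparison = {
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "verdict": cmp.verdict,
                "pdf_induced": {str(k): v for k, v in cmp.pdf1.items()},
                "pdf_background": {str(k): v for k, v in cmp.pdf2.items()},
            }
        manifest["stages_done"].append(stage)

        stage = "community_detection"
        partition = None
        if matched and sub.m >= 1:
            partition, history = community_mod.greedy_modularity(sub.network)
            report.communities = {
                "k": partition.k,
                "Q": partition.Q,
                "sizes": partition.sizes(),
                "n_merges": len(history.steps),
                "best_step": history.best_step,
            }
            pd.DataFrame(
                sorted(partition.assignment.items()), columns=["node", "community"]
            ).to_csv(out / "partition.tsv", sep="\t", index=False)
            mat, ordering, boundaries = community_mod.community_adjacency(
                sub.network, partition
            )
            pd.DataFrame(mat, index=ordering, columns=ordering).to_csv(
                out / "adjacency_community_order.tsv", sep="\t"
            )
            (out / "community_boundaries.json").write_text(
                json.dumps({"ordering": ordering, "boundaries": boundaries}) + "\n"
            )
            if config.write_heatmap:
                community_mod.plot_adjacency_heatmap(
                    sub.network, partition, str(out / "adjacency_heatmap.png")
                )
            logger.info("communities: k=%d Q=%.4f", partition.k, partition.Q)
        manifest["stages_done"].append(stage)

        stage = "enrichment"
        libraries = [io_mod.read_gmt(p) for p in config.gmt_libraries]
        # universe policy: "library" -> each library's own universe (None);
        # otherwise a path to a one-symbol-per-line universe file.
        universe = (
            None
            if config.universe == "library"
            else io_mod.read_gene_list(str(config.universe)).as_set()
        )
        for lib in libraries:
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                try:
                    results = enrichment_mod.fisher_enrichment(
                        hits, lib, universe=universe
                    )
                except ValueError as exc:
                    caught.append(f"list enrichment vs {lib.name}: {exc}")
                    continue
                caught.extend(str(w.message) for w in wrec)
            report.list_enrichment[lib.name] = [_result_dict(r) for r in results]
            _enrichment_frame(results).to_csv(
                out / f"enrichment_list_{lib.name}.tsv", sep="\t", index=False
            )
        if partition is not None and libraries:
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                annotations = enrichment_mod.annotate_clusters(
                    partition,
                    libraries,
                    universe=universe,
                    min_cluster_size=config.min_cluster_size,
                )
                caught.extend(str(w.message) for w in wrec)
            for cid, per_lib in annotations.items():
                for lib_name, results in per_lib.items():
                    _enrichment_frame(results).to_csv(
                        out / f"enrichment_cluster{cid}_{lib_name}.tsv",
                        sep="\t",
                        index=False,
                    )
            tops = enrichment_mod.top_terms(annotations)
            report.cluster_top_terms = {
                str(cid): {lib: _result_dict(r) for lib, r in per_lib.items()}
                for cid, per_lib in tops.items()
            }
        manifest["stages_done"].append(stage)

        stage = "disease_lookup"
        if config.disease_library:
            disease_lib = io_mod.read_gmt(config.disease_library)
            report.disease_table = enrichment_mod.disease_lookup(hits, disease_lib)
            pd.DataFrame(
                [
                    {"disease": term, "genes": ";".join(genes)}
                    for term, genes in report.disease_table.items()
                ],
                columns=["disease", "genes"],
            ).to_csv(out / "disease_table.tsv", sep="\t", index=False)
        manifest["stages_done"].append(stage)

        stage = "cross_screen_overlap"
        if config.second_hit_list:
            second = io_mod.read_gene_list(config.second_hit_list)
            if config.ortholog_map:
                second = second.map_orthologs(
                    io_mod.read_ortholog_map(config.ortholog_map)
                )
            res = enrichment_mod.overlap_test(
                hits, second, universe_size=config.overlap_universe_size
            )
            report.overlap = _result_dict(res)
            logger.info("cross-screen overlap: k=%d p=%.3g", res.table.k, res.p)
        manifest["stages_done"].append(stage)

        report.warnings_issued = caught
        report.to_json(out / "report.json")
        manifest["complete"] = True
        save_manifest()
        logger.info("run complete: %s", out)
        return report
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        save_manifest()
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
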
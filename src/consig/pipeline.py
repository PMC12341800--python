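"""End-to-end orchestration: filter -> consensus -> score -> profile.

A single YAML config describes inputs, parameters and the output
directory; stages whose inputs are absent from the config are skipped.
Every run writes a manifest (package version, parameters, SHA-256
checksums of inputs and outputs) sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .consensus import (
    ConsensusParams,
    CountingUnit,
    FilterParams,
    Linkage,
    SimilarityMetric,
    consensus_signature,
    exclusive_intersections,
    filter_markers,
    gene_lists_by_class,
    hierarchical_cluster,
    pairwise_similarity,
    similarity_to_distance,
)
from .datatypes import CellClass, FCScale, LayerTag, ValidationError
from . import io as cio
from .pseudotime import profile_signature
from .scoring import (
    ScoreMethod,
    ScoreParams,
    rank_signature_score,
    summarize_by_cluster,
    zscore_signature_score,
)

logger = logging.getLogger("consig")

# distinct exit codes per failing stage
EXIT_CONFIG, EXIT_FILTER, EXIT_CONSENSUS, EXIT_SCORE, EXIT_PROFILE = 2, 10, 11, 12, 13


class StageError(RuntimeError):
    def __init__(self, stage: str, exit_code: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = exit_code
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Parsed pipeline configuration (see ``RunConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    markers: Mapping[str, Any] | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    consensus: Mapping[str, Any] | None = None
    expression: Mapping[str, Any] | None = None
    score: Mapping[str, Any] | None = None
    profile: Mapping[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ValidationError("config lacks output_dir")
        fp = raw.get("filter", {}) or {}
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            markers=raw.get("markers"),
            filter_params=FilterParams(
                fc_min_linear=float(fp.get("fc_min_linear", 1.5)),
                p_adj_max=float(fp.get("p_adj_max", 0.05)),
                ln_fc_min=float(fp.get("ln_fc_min", 0.25))),
            consensus=raw.get("consensus"),
            expression=raw.get("expression"),
            score=raw.get("score"),
            profile=raw.get("profile"),
        )

    def input_paths(self) -> list[Path]:
        paths: list[Path] = []
        if self.markers:
            paths.append(Path(self.markers["path"]))
        if self.expression:
            for key in ("mtx", "genes", "cells", "dense", "annotation"):
                if self.expression.get(key):
                    paths.append(Path(self.expression[key]))
        if self.score and self.score.get("signature_gmt"):
            paths.append(Path(self.score["signature_gmt"]))
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _fc_scales(spec: Any) -> FCScale | dict[str, FCScale]:
    if isinstance(spec, str):
        return FCScale[spec.upper()]
    if isinstance(spec, Mapping):
        return {k: FCScale[v.upper()] for k, v in spec.items()}
    return FCScale.LINEAR


def _load_expression(section: Mapping[str, Any]):
    layer = LayerTag[str(section.get("layer", "COUNTS")).upper()]
    if section.get("dense"):
        return cio.read_expression_dense(section["dense"], layer)
    return cio.read_expression_mtx(section["mtx"], section["genes"],
                                   section["cells"], layer)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and return the run manifest."""
    missing = [str(p) for p in cfg.input_paths() if not p.exists()]
    if missing:
        raise StageError("preflight", EXIT_CONFIG,
                         FileNotFoundError(f"missing inputs: {missing}"))
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "consig",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "filter": vars(cfg.filter_params),
            "consensus": dict(cfg.consensus or {}),
            "score": dict(cfg.score or {}),
            "profile": dict(cfg.profile or {}),
        },
        "inputs": {str(p): _sha256(p) for p in cfg.input_paths()},
        "stages_run": [],
        "outputs": {},
    }

    def record(path: Path) -> None:
        manifest["outputs"][str(path)] = _sha256(path)

    filtered = None
    if cfg.markers:
        try:
            logger.info("=== stage: filter ===")
            table = cio.read_marker_table(
                cfg.markers["path"], _fc_scales(cfg.markers.get("fc_scale")))
            filtered = filter_markers(table, cfg.filter_params)
            path = out / "filtered_markers.tsv"
            cio.write_marker_table(filtered, path)
            record(path)
            manifest["stages_run"].append("filter")
        except StageError:
            raise
        except Exception as e:
            raise StageError("filter", EXIT_FILTER, e) from e

    if filtered is not None and cfg.consensus:
        try:
            logger.info("=== stage: consensus ===")
            section = cfg.consensus
            metric = SimilarityMetric[str(section.get("metric", "JACCARD")).upper()]
            linkage = Linkage[str(section.get("linkage", "COMPLETE")).upper()]
            unit = CountingUnit[str(section.get("counting_unit", "STUDY")).upper()]
            min_studies = section.get("min_studies", {})
            for cls_name in section.get("classes", ["NSC"]):
                cls = CellClass[cls_name.upper()]
                lists = gene_lists_by_class(filtered, cls, unit)
                if not lists:
                    logger.warning("no %s lists after filtering; skipped", cls.value)
                    continue
                k = int(min_studies.get(cls_name, section.get("k", 5))
                        if isinstance(min_studies, Mapping) else min_studies)
                sig = consensus_signature(
                    lists, ConsensusParams(k, unit), name=f"{cls.value}_consensus")
                gmt = out / f"consensus_{cls.value}.gmt"
                cio.write_gmt([sig], gmt)
                record(gmt)
                S = pairwise_similarity(lists, metric)
                sim_path = out / f"similarity_{cls.value}.tsv"
                S.to_frame().to_csv(sim_path, sep="\t")
                record(sim_path)
                if len(lists) >= 2:
                    D = similarity_to_distance(S)
                    dend = hierarchical_cluster(D, S.labels, linkage)
                    nwk = out / f"dendrogram_{cls.value}.nwk"
                    nwk.write_text(dend.to_newick() + "\n", encoding="utf-8")
                    record(nwk)
                upset = exclusive_intersections(lists)
                upset_path = out / f"upset_{cls.value}.tsv"
                upset.to_frame().to_csv(upset_path, sep="\t", index=False)
                record(upset_path)
            manifest["stages_run"].append("consensus")
        except StageError:
            raise
        except Exception as e:
            raise StageError("consensus", EXIT_CONSENSUS, e) from e

    scores = None
    ann = None
    if cfg.expression and cfg.score:
        try:
            logger.info("=== stage: score ===")
            expr = _load_expression(cfg.expression)
            if cfg.expression.get("annotation"):
                ann = cio.read_cell_annotation(cfg.expression["annotation"])
                ann.validate_against(expr)
            sig = cio.read_gmt(cfg.score["signature_gmt"])[0]
            method = str(cfg.score.get("method", "rank")).lower()
            if method == "rank":
                params = ScoreParams(
                    max_rank=int(cfg.score.get("max_rank", 1500)),
                    cutoff=float(cfg.score.get("cutoff", 0.4)))
                scores = rank_signature_score(expr, sig, params)
            else:
                scores = zscore_signature_score(expr, sig)
            df = scores.scores.to_frame()
            if scores.high_flag is not None:
                df["high_flag"] = scores.high_flag
            path = out / "scores.tsv"
            df.to_csv(path, sep="\t", index_label="cell_id")
            record(path)
            if ann is not None:
                summary = summarize_by_cluster(expr, ann, sig)
                spath = out / "cluster_summary.tsv"
                summary.frame.to_csv(spath, sep="\t", index=False)
                record(spath)
            manifest["stages_run"].append("score")
        except StageError:
            raise
        except Exception as e:
            raise StageError("score", EXIT_SCORE, e) from e

    if scores is not None and ann is not None and cfg.profile is not None \
            and "pseudotime" in ann.frame.columns:
        try:
            logger.info("=== stage: profile ===")
            prof = profile_signature(
                scores, ann,
                n_bins=int(cfg.profile.get("n_bins", 50)),
                smooth_window=cfg.profile.get("smooth_window"))
            path = out / "profile.tsv"
            prof.to_frame().to_csv(path, sep="\t", index=False)
            record(path)
            manifest["stages_run"].append("profile")
        except StageError:
            raise
        except Exception as e:
            raise StageError("profile", EXIT_PROFILE, e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                             encoding="utf-8")
    logger.info("run complete; manifest at %s", manifest_path)
    return manifest
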
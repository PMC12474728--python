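"""End-to-end orchestration: simulate (or load) → filter → match → normalize
→ bivariate screen → consensus selection → classification trees → report.

A single run seed fans out into per-stage seeds (stage-name hashed) so any
stage can be re-run reproducibly in isolation; identical config + seed yields
a byte-identical consolidated report. All intermediate artifacts are plain
CSV/JSON so each stage is independently inspectable.
"""

from __future__ import annotations

import hashlib
import json
import time
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bivariate import effect_table, rank_markers
from .config import (
    EARLY_PANEL,
    GROUP_CASE,
    LATE_PANEL,
    SyntheticConfig,
    default_paper_config,
)
from .consensus import ConsensusImportanceSelector, BOOSTING_DEFAULTS, FOREST_DEFAULTS
from .errors import ConfigurationError, MetabopanelError
from .matching import match_cohort
from .normalize import MetaboliteMatrix, filter_endogenous, normalize, read_subjects
from .simulate import generate_cohort, write_cohort
from .tree import compare_panels

logger = logging.getLogger("metabopanel")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the run seed and the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run. ``seed`` is mandatory; every stage
    parameter is echoed verbatim into the report."""

    seed: int
    synthetic: bool = True
    cohort: SyntheticConfig | None = None
    subjects_csv: str | None = None
    matrix_csv: str | None = None
    annotations_csv: str | None = None
    policy: str = "optimal"
    k: int = 30
    elbow: bool = False
    max_depth: int = 5
    min_leaf: int = 5
    panel_late: tuple[str, ...] | None = None
    panel_early: tuple[str, ...] | None = None
    n_trees: int = FOREST_DEFAULTS["n_trees"]
    n_stages: int = BOOSTING_DEFAULTS["n_stages"]

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if not self.synthetic and not (
            self.subjects_csv and self.matrix_csv and self.annotations_csv
        ):
            raise ConfigurationError(
                "non-synthetic runs need subjects, matrix and annotations CSVs"
            )


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if isinstance(exc, MetabopanelError) and not str(exc).startswith("["):
                    raise type(exc)(f"[{name}] {exc}") from exc
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _StageContext()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in order, writing artifacts under ``outdir``.

    Returns the consolidated run report (also written to report.json).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": {"name": "metabopanel", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": _config_echo(config),
        "stages": {},
    }

    with _stage("simulate"):
        if config.synthetic:
            cohort_cfg = config.cohort or default_paper_config()
            cohort_cfg = replace(cohort_cfg, seed=stage_seed(config.seed, "simulate"))
            subjects, matrix, truth = generate_cohort(cohort_cfg)
            write_cohort(outdir / "cohort", subjects, matrix, truth)
            report["stages"]["simulate"] = {
                "n_cases": cohort_cfg.n_cases,
                "n_control_pool": cohort_cfg.n_control_pool,
                "n_metabolites": cohort_cfg.n_metabolites,
                "planted_markers": dict(cohort_cfg.planted_markers),
                "seed": cohort_cfg.seed,
            }
        else:
            subjects = read_subjects(config.subjects_csv)
            matrix = MetaboliteMatrix.from_csv(config.matrix_csv, config.annotations_csv)
            report["stages"]["simulate"] = {"source": "files", "n_samples": len(subjects)}

    with _stage("filter"):
        n_before = len(matrix.metabolites)
        matrix = filter_endogenous(matrix)
        report["stages"]["filter"] = {
            "n_columns_in": n_before,
            "n_endogenous": len(matrix.metabolites),
        }

    with _stage("match"):
        matches = match_cohort(subjects, policy=config.policy)
        matches.to_frame().to_csv(outdir / "pairs.csv", index=False)
        match_summary = {
            "n_pairs": len(matches.pairs),
            "mean_score": matches.mean,
            "sd_score": matches.sd,
            "policy": matches.policy,
        }
        _json_dump(match_summary, outdir / "match_summary.json")
        report["stages"]["match"] = match_summary

    with _stage("normalize"):
        analyzed = matches.case_ids + matches.control_ids
        matrix = normalize(matrix.subset_samples(analyzed), subjects)
        matrix.values.rename_axis("sample_id").to_csv(outdir / "normalized.csv")
        report["stages"]["normalize"] = {
            "n_samples": len(matrix.sample_ids),
            "state": matrix.state,
        }
        labels = subjects.loc[matrix.sample_ids, "group"]
        is_case = (labels == GROUP_CASE).to_numpy()

    with _stage("screen"):
        effects = effect_table(matrix.values, is_case, matrix.annotations)
        effects.to_csv(outdir / "effects.csv", index=False)
        ranking = rank_markers(matrix.values, is_case)
        ranking.to_csv(outdir / "ranking.csv")
        report["stages"]["screen"] = {
            "n_nominal_p_lt_05": int((effects["nominal_p"] < 0.05).sum()),
            "top_accuracy": float(ranking["accuracy"].iloc[0]),
            "top_metabolites": list(ranking["metabolite"].head(3)),
        }

    with _stage("select"):
        selector = ConsensusImportanceSelector(
            k=config.k,
            elbow=config.elbow,
            n_trees=config.n_trees,
            n_stages=config.n_stages,
            random_state=stage_seed(config.seed, "select"),
        ).fit(matrix.values, is_case)
        selector.importance_table_.to_csv(outdir / "importance.csv")
        consensus = selector.consensus_
        _json_dump(consensus.to_dict(), outdir / "consensus.json")
        for crit in ("perm_importance", "gini_worsening", "relative_influence"):
            scree = selector.importance_table_[crit].sort_values(ascending=False)
            scree.to_csv(outdir / f"scree_{crit}.csv")
        report["stages"]["select"] = {
            "k": consensus.k,
            "n_union": len(consensus.union),
            "n_at_least_two": len(consensus.at_least_two),
            "n_intersection": len(consensus.intersection),
            "candidates": list(consensus.candidates),
        }

    with _stage("tree"):
        panel_late = list(config.panel_late) if config.panel_late else None
        if panel_late is None:
            # discovery flow: model on the consensus candidates; fall back to
            # the fixed consensus panel if the intersection is degenerate
            panel_late = (
                list(consensus.candidates)
                if len(consensus.candidates) >= 2
                else list(LATE_PANEL)
            )
            panel_late = [m for m in panel_late if m in matrix.values.columns]
        panel_early = list(config.panel_early) if config.panel_early else [
            m for m in EARLY_PANEL if m in matrix.values.columns
        ]
        results = compare_panels(
            matrix.values,
            is_case,
            panel_late=panel_late,
            panel_early=panel_early,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_leaf,
        )
        table2_rows = []
        tree_report = {}
        for name, res in results.items():
            res["tree"].to_json(outdir / f"tree_{name}.json")
            (outdir / f"tree_{name}.txt").write_text(res["tree"].to_text() + "\n")
            m = res["report"]
            assert m.unweighted_accuracy == (m.sensitivity + m.specificity) / 2
            tree_report[name] = m.to_dict()
            table2_rows.append(
                {
                    "panel": name,
                    "sensitivity_pct": round(m.sensitivity, 1),
                    "specificity_pct": round(m.specificity, 1),
                    "unweighted_accuracy_pct": round(m.unweighted_accuracy, 1),
                    "roc_auc": round(m.auc, 3),
                }
            )
        pd.DataFrame(table2_rows).to_csv(outdir / "panel_metrics.csv", index=False)
        _json_dump(tree_report, outdir / "metrics.json")
        report["stages"]["tree"] = {
            "panel_late": panel_late,
            "panel_early": panel_early,
            "metrics": tree_report,
        }

    _json_dump(report, outdir / "report.json")
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    if config.cohort is not None:
        echo["cohort"] = asdict(config.cohort)
    return echo
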
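"""End-to-end analysis pipeline and run configuration.

Stages: load -> binarize nominal attributes -> discretize the f2 decision
-> two-copy gain/cost transformation -> rough approximations -> rule
induction for both class unions -> VC-bagged cross-validation -> attribute
relevance.  Reports are written as CSV/Markdown (rule tables in the
published column layout), JSON (approximations, CV summary) and a
provenance log carrying the exact configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .approximations import approximation_report, downward, upward
from .ensemble import attribute_relevance, cross_validate, vc_bagging_train
from .information_system import (
    DecisionTable,
    binarize_all_nominal,
    clone_gain_cost,
    discretize_decision,
    load_table,
    schema_from_yaml,
)
from .rules import induce_rules

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one end-to-end run; defaults follow the study design
    (f2 threshold 50, 5-fold CV repeated 100 times)."""

    table_csv: str | None = None
    schema_yaml: str | None = None
    f2_threshold: float = 50.0
    consistency: float = 1.0
    k: int = 5
    repeats: int = 100
    n_bags: int = 30
    seed: int = 0
    measure: str = "s"
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _markdown_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def prepare_table(table: DecisionTable, f2_threshold: float = 50.0) -> DecisionTable:
    """Binarize, discretize and two-copy transform a raw decision table.

    Tables that already carry integer class labels skip discretization.
    """
    table = binarize_all_nominal(table)
    dec = table.decision
    is_class = set(pd.unique(dec)) <= {1, 2} or table.decision_name == "class"
    if not is_class:
        table = discretize_decision(table, threshold=f2_threshold)
    return clone_gain_cost(table)


def run_pipeline(config: RunConfig, table: DecisionTable | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the in-memory results (prepared table, rule sets,
    approximation report, CV report, relevance series, output paths).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        if table is None:
            if config.table_csv is None or config.schema_yaml is None:
                raise ValueError("run_pipeline needs table_csv and schema_yaml (or a table)")
            attrs, decision = schema_from_yaml(config.schema_yaml)
            table = load_table(config.table_csv, attrs, decision=decision)

        current = stage("prepare")
        prepared = prepare_table(table, config.f2_threshold)

        current = stage("approximations")
        approx = approximation_report(prepared)
        (outdir / "approximations.json").write_text(json.dumps(approx, indent=2))

        current = stage("rule induction")
        classes = prepared.classes
        rulesets = {}
        for c, union in ((classes[0], upward(classes[0])), (classes[-1], downward(classes[-1]))):
            rs = induce_rules(prepared, union, config.consistency, config.measure)
            rulesets[c] = rs
            df = rs.to_dataframe()
            df.to_csv(outdir / f"rules_class{c}.csv", index=False)
            md = _markdown_table(df) if len(df) else "(no rules)\n"
            (outdir / f"rules_class{c}.md").write_text(md)

        current = stage("cross-validation")
        cv = cross_validate(
            prepared,
            k=config.k,
            repeats=config.repeats,
            n_bags=config.n_bags,
            consistency=config.consistency,
            seed=config.seed,
            measure=config.measure,
        )
        cv.to_dataframe().to_csv(outdir / "cv_folds.csv", index=False)
        (outdir / "cv_summary.json").write_text(json.dumps(cv.summary(), indent=2))

        current = stage("relevance")
        ensemble = vc_bagging_train(
            prepared,
            n_bags=config.n_bags,
            consistency=config.consistency,
            seed=config.seed,
            measure=config.measure,
        )
        relevance = attribute_relevance(ensemble, prepared)
        relevance.to_csv(outdir / "relevance.csv", header=True)
    except Exception as err:  # tag errors with the failing stage
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_objects": prepared.n_objects,
        "gamma": approx["gamma"],
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))

    return {
        "table": prepared,
        "approximations": approx,
        "rulesets": rulesets,
        "cv": cv,
        "relevance": relevance,
        "outdir": outdir,
    }
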
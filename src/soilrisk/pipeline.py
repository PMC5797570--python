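"""End-to-end orchestration: transform → factors → fits → report.

``run_pipeline`` executes the whole analysis on files in the io dialects
and writes every artefact plus a machine-readable manifest (config
snapshot, input digests, per-stage status/timing, outputs, seed), so any
run can be reproduced or resumed from its failure point.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compositional import transform as apply_transform
from .exceptions import FormatError, SoilRiskError, ValidationError
from .factor import PrincipalFactorAnalysis
from .io import (
    PipelineConfig,
    read_adjacency,
    read_soil_table,
    write_score_table,
    write_transformed_table,
)
from .model import run_endpoint_battery
from .tables import TownTable

__all__ = ["RunManifest", "run_pipeline", "write_rr_report",
           "read_town_groups"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def record(self, name: str, status: str, seconds: float,
               detail: str = "") -> None:
        self.stages.append(
            {"stage": name, "status": status,
             "seconds": round(seconds, 3), "detail": detail}
        )

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_town_groups(path) -> dict:
    """Town tables keyed by (endpoint, sex).

    towns.csv may carry optional ``endpoint`` and ``sex`` columns; without
    them the file is a single ('all', 'both') group.  All groups must share
    the same town ids (they share one adjacency structure).
    """
    df = pd.read_csv(path, comment="#")
    group_cols = [c for c in ("endpoint", "sex") if c in df.columns]
    if not group_cols:
        df = df.assign(endpoint="all", sex="both")
    elif "endpoint" not in df.columns:
        df = df.assign(endpoint="all")
    elif "sex" not in df.columns:
        df = df.assign(sex="both")
    required = ["town_id", "x", "y", "observed", "expected"]
    missing = [c for c in required if c not in df.columns]
    if missing or len(df) == 0:
        raise FormatError(
            f"{path}: town table is empty or lacks columns {missing}"
        )
    reserved = required + ["endpoint", "sex"]
    covs = [c for c in df.columns if c not in reserved]
    groups = {}
    ref_ids = None
    for (endpoint, sex), sub in df.groupby(["endpoint", "sex"], sort=True):
        ids = [str(t) for t in sub["town_id"]]
        if ref_ids is None:
            ref_ids = ids
        elif ids != ref_ids:
            raise ValidationError(
                f"town ids of group ({endpoint}, {sex}) differ from the "
                "first group"
            )
        groups[(str(endpoint), str(sex))] = TownTable(
            town_id=sub["town_id"].to_numpy(),
            coords=sub[["x", "y"]].to_numpy(float),
            observed=sub["observed"].to_numpy(),
            expected=sub["expected"].to_numpy(float),
            covariates=sub[covs].to_numpy(float) if covs else None,
            covariate_names=covs,
        )
    return groups


def write_rr_report(rows: pd.DataFrame, csv_path, labels=None) -> str:
    """Write the RR table CSV (sorted by endpoint, sex, factor) and return
    a text summary listing every association whose 95% interval excludes 1."""
    if len(rows) == 0:
        raise ValidationError("empty RR table")
    rows = rows.sort_values(["endpoint", "sex", "factor"]).reset_index(drop=True)
    rows.to_csv(csv_path, index=False)
    label_of = dict(labels or {})
    flagged = rows[rows["excludes_one"] & (rows["status"] == "ok")] \
        if "status" in rows.columns else rows[rows["excludes_one"]]
    lines = [f"RR report: {len(rows)} fits "
             f"({int(rows['excludes_one'].sum())} flagged)"]
    if len(flagged) == 0:
        lines.append("no associations flagged")
    for _, r in flagged.iterrows():
        lab = label_of.get(r["factor"])
        factor = f"{r['factor']} ({lab})" if lab else str(r["factor"])
        lines.append(
            f"{r['endpoint']} / {r['sex']} / {factor}: "
            f"RR {r['RR']:.3f} (95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f})"
        )
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, seed: int | None = None,
                 base_dir=".") -> RunManifest:
    """Run transform → factor analysis → endpoint battery → report.

    When covariates are present and ``config.adjusted`` is true, both the
    crude and the adjusted battery run (so the confounding comparison is
    available); the naïve two-stage comparator runs when ``config.naive``.
    Stage failure is recorded in the manifest and downstream stages skip.
    """
    base = Path(base_dir)
    out = base / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.inference.seed
    manifest = RunManifest(config=config.to_dict(), seed=int(seed))

    for key in ("soil", "towns", "adjacency"):
        p = base / getattr(config, key)
        if p.exists():
            manifest.input_digests[key] = _digest(p)

    state = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest.record(name, "ok", time.perf_counter() - t0)
            return True
        except (SoilRiskError, OSError, ValueError) as exc:
            manifest.record(name, "failed", time.perf_counter() - t0, str(exc))
            return False

    def do_transform():
        soil = read_soil_table(base / config.soil)
        state["transformed"] = apply_transform(soil, config.transform)
        path = out / "transformed.csv"
        write_transformed_table(state["transformed"], path)
        manifest.outputs.append(str(path))

    def do_factors():
        fa = PrincipalFactorAnalysis(
            state["transformed"], variance_threshold=config.variance_threshold
        )
        results = fa.fit()
        state["factors"] = results
        state["scores"] = results.scores(state["transformed"])
        loadings_path = out / "loadings.csv"
        results.loadings_frame().to_csv(loadings_path)
        scores_path = out / "scores.csv"
        write_score_table(state["scores"], scores_path)
        labels_path = out / "factor_labels.txt"
        with open(labels_path, "w", encoding="utf-8") as fh:
            fh.write(results.summary() + "\n")
        manifest.outputs.extend(
            [str(loadings_path), str(scores_path), str(labels_path)]
        )

    def do_fits():
        groups = read_town_groups(base / config.towns)
        first = next(iter(groups.values()))
        graph = read_adjacency(base / config.adjacency, first.town_id)
        variants = [("adjusted", True)] if config.adjusted else []
        has_covs = first.covariates.shape[1] > 0
        if config.adjusted and has_covs:
            variants.append(("crude", False))
        if not variants:
            variants = [("crude", False)]
        tables = []
        for tag, adjusted in variants:
            methods = ["joint"] + (["naive"] if config.naive else [])
            for method in methods:
                rr = run_endpoint_battery(
                    state["scores"], groups, graph,
                    mesh_config=config.mesh, adjusted=adjusted,
                    method=method, inference=config.inference, seed=seed,
                )
                rr.insert(0, "model", f"{tag}-{method}")
                tables.append(rr)
        state["rr"] = pd.concat(tables, ignore_index=True)

    def do_report():
        rr = state["rr"]
        labels = dict(zip(state["factors"].factor_names,
                          state["factors"].labels()))
        csv_path = out / "rr_report.csv"
        summary = write_rr_report(rr, csv_path, labels=labels)
        txt_path = out / "rr_summary.txt"
        with open(txt_path, "w", encoding="utf-8") as fh:
            fh.write(summary + "\n")
        manifest.outputs.extend([str(csv_path), str(txt_path)])

    pipeline = [("transform", do_transform), ("factors", do_factors),
                ("fit", do_fits), ("report", do_report)]
    for name, fn in pipeline:
        if not stage(name, fn):
            for later, _ in pipeline[pipeline.index((name, fn)) + 1:]:
                manifest.record(later, "skipped", 0.0)
            break

    manifest.write(out / "manifest.json")
    return manifest
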
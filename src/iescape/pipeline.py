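"""End-to-end orchestration: score -> stage -> deconvolve -> survival.

A run is described by a :class:`RunConfig` (built directly or from a
YAML document), validated fail-fast before any compute, and executed by
:func:`run_pipeline`, which writes per-stage outputs plus a provenance
manifest (input hashes, parameters, seed, package version) sufficient to
re-run the pipeline identically.  Any stage failure aborts the run with
the failing stage named and removes the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deconvolution import SignatureMatrix, fit_fractions
from .enrichment import score_axes
from .io import read_expression, read_gmt
from .staging import assign_stage, stage_summary
from .survival import dichotomize_marker, km_estimate, logrank_test

logger = logging.getLogger("iescape")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; file paths validated up front."""

    expression: str
    gene_sets: str
    outdir: str
    iegs_name: str = "IEGS33"
    tact_name: str = "TCELL_ACTIVATION"
    groups: str | None = None  # CSV sample_id,group (else one 'all' group)
    signature: str | None = None  # TSV -> deconvolution stage
    clinical: str | None = None  # CSV sample_id,time,event[,group] -> survival
    markers: str | None = None  # CSV sample_id,marker,compartment,percent_positive
    weight_exponent: float = 0.25
    null_draws: int = 1000
    thresholds: tuple[float, float] | None = None  # explicit; else random-null
    solver: str = "nnls"
    cutoff_me: float = 10.0
    cutoff_tumor: float = 20.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "thresholds" in doc and doc["thresholds"] is not None:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(**doc)

    def validate(self) -> None:
        for name in ("expression", "gene_sets", "signature", "clinical",
                     "markers", "groups"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p} does not exist")
        if self.null_draws < 1:
            raise ValueError("null_draws must be >= 1")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every configured stage and return the output paths.

    Always: staging (stage CSV + composition summary).  Optional:
    deconvolution (if a signature is configured), survival by group and
    by dichotomized marker (if clinical / marker tables are configured).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    current_stage = "setup"

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        current_stage = "read inputs"
        matrix = read_expression(config.expression)
        sets = {gs.name: gs for gs in read_gmt(config.gene_sets)}
        for name in (config.iegs_name, config.tact_name):
            if name not in sets:
                raise ValueError(f"gene set {name!r} not in {config.gene_sets}")
        groups = None
        if config.groups:
            gdf = pd.read_csv(config.groups)
            groups = gdf.set_index("sample_id")["group"]

        current_stage = "score and stage"
        axes = score_axes(
            matrix, sets[config.iegs_name], sets[config.tact_name],
            thresholds=config.thresholds, n_draws=config.null_draws,
            seed=config.seed, weight_exponent=config.weight_exponent,
        )
        assignment = assign_stage(axes, groups=groups)
        assignment.table.to_csv(emit("stages.csv"), index_label="sample_id")
        summary = stage_summary(assignment)
        summary.to_csv(emit("stage_summary.csv"), index=False)
        with open(emit("stage_summary.json"), "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "thresholds": {"iegs33": axes.thr_iegs33,
                                   "tact": axes.thr_tact},
                    "composition": summary.to_dict(orient="records"),
                },
                fh, indent=2,
            )

        if config.signature:
            current_stage = "deconvolution"
            sig = SignatureMatrix(
                pd.read_csv(config.signature, sep="\t", index_col=0)
            )
            fracs = fit_fractions(
                sig, matrix, solver=config.solver, scale="log2_input"
            )
            fracs.data.to_csv(
                emit("fractions.tsv"), sep="\t", index_label="sample_id"
            )

        survival_report: dict = {}
        clinical = None
        if config.clinical:
            current_stage = "survival by group"
            clinical = pd.read_csv(config.clinical).rename(
                columns={"time_months": "time"}
            )
            if "group" not in clinical.columns:
                clinical["group"] = "all"
            clinical = clinical[["sample_id", "time", "event", "group"]]
            # stage-based grouping from this run's assignment
            stage_of = assignment.table["stage"]
            by_stage = clinical.assign(
                group=clinical["sample_id"].map(stage_of).astype("Int64").astype(str)
            ).dropna(subset=["group"])
            chi2, df_, p = logrank_test(by_stage)
            curves = {}
            for stage, sub in by_stage.groupby("group"):
                km = km_estimate(sub)
                curves[f"stage_{stage}"] = {
                    "s60": km.survival_at(60.0),
                    "ci60": km.ci_at(60.0),
                    "n": int(len(sub)),
                }
            survival_report["by_stage"] = {
                "logrank_chi2": chi2, "df": df_, "p": p, "curves": curves,
            }

        if config.markers:
            current_stage = "marker dichotomization"
            mk = pd.read_csv(config.markers)
            labels = dichotomize_marker(
                mk, cutoff_me=config.cutoff_me, cutoff_tumor=config.cutoff_tumor
            )
            labels.to_csv(emit("markers_dichotomized.csv"), index=False)
            if clinical is not None:
                current_stage = "survival by marker"
                survival_report["by_marker"] = {}
                for (marker, comp), sub in labels.groupby(
                    ["marker", "compartment"]
                ):
                    merged = clinical.merge(
                        sub[["sample_id", "label"]], on="sample_id"
                    ).assign(group=lambda d: d["label"])
                    if merged["group"].nunique() < 2:
                        continue
                    chi2, df_, p = logrank_test(merged)
                    survival_report["by_marker"][f"{marker}:{comp}"] = {
                        "logrank_chi2": chi2, "df": df_, "p": p,
                        "n_high": int((merged["group"] == "high").sum()),
                        "n_low": int((merged["group"] == "low").sum()),
                    }

        if survival_report:
            with open(emit("survival.json"), "w", encoding="utf-8") as fh:
                json.dump(survival_report, fh, indent=2)

        current_stage = "manifest"
        manifest = {
            "iescape_version": __version__,
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in (
                    ("expression", config.expression),
                    ("gene_sets", config.gene_sets),
                    ("signature", config.signature),
                    ("clinical", config.clinical),
                    ("markers", config.markers),
                    ("groups", config.groups),
                )
                if p
            },
        }
        with open(emit("manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    return {p.name: p for p in written}
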
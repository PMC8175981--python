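"""Corpus TSV and config reading, report serialization, run manifests.

Corpora travel as UTF-8 TSV with the header
``speaker_id<TAB>group<TAB>object_id<TAB>token`` (TSV rather than CSV so
labels containing commas survive round-trips). Configs are YAML or JSON
validated against a strict schema (unknown keys rejected). Reports are
written as CSV tables (6 significant digits) plus full-precision JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .errors import ValidationError
from .experiments import Sim1Report, Sim2Report
from .inference import CategoricalDistribution, GibbsSettings
from .model import Corpus, GroupSpec, LabelingEvent, LabelSpace

__all__ = [
    "CORPUS_COLUMNS",
    "RunConfig",
    "read_config",
    "read_corpus",
    "write_corpus",
    "write_report",
    "write_manifest",
]

CORPUS_COLUMNS = ("speaker_id", "group", "object_id", "token")


class RunConfig(BaseModel):
    """Validated model configuration.

    ``labels``: the ordered candidate-label space. ``groups``: group name
    -> characteristic knowledgeability theta. ``k_prior``: per-speaker
    knowledgeability prior used when group membership is inferred rather
    than observed. ``label_prior`` is uniform in this release.
    """

    model_config = ConfigDict(extra="forbid")

    labels: list[str] = Field(min_length=1)
    groups: dict[str, float] = Field(default_factory=dict)
    label_prior: Literal["uniform"] = "uniform"
    k_prior: float = 0.5
    method: Literal["exact", "gibbs"] = "exact"
    samples: int = 20_000
    burn_in: int = 2_000
    seed: int = 0
    log_base: float = 2.0

    @field_validator("labels")
    @classmethod
    def _unique(cls, v: list[str]) -> list[str]:
        if len(set(v)) != len(v):
            raise ValueError("labels must be unique")
        return v

    @field_validator("groups")
    @classmethod
    def _theta_range(cls, v: dict[str, float]) -> dict[str, float]:
        for name, theta in v.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"theta for group {name!r} outside [0, 1]")
        return v

    @field_validator("k_prior")
    @classmethod
    def _prior_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("k_prior must lie in [0, 1]")
        return v

    def label_space(self) -> LabelSpace:
        return LabelSpace(tuple(self.labels))

    def group_specs(self) -> dict[str, GroupSpec]:
        return {name: GroupSpec(name, theta) for name, theta in self.groups.items()}

    def gibbs_settings(self) -> GibbsSettings:
        return GibbsSettings(samples=self.samples, burn_in=self.burn_in, seed=self.seed)


def read_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON model config."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a mapping")
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ValidationError(f"invalid config {path}: {exc}") from exc


def read_corpus(
    path: str | Path,
    label_space: LabelSpace | None = None,
    groups: Mapping[str, GroupSpec] | None = None,
) -> Corpus:
    """Read and validate a corpus TSV.

    If no label space is supplied, the space is the sorted set of tokens
    observed in the file. Consistency violations are reported with the
    offending row numbers by corpus validation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; expected header "
            + "\t".join(CORPUS_COLUMNS)
        )
    if label_space is None:
        label_space = LabelSpace(tuple(sorted(set(df["token"]))))
    events = tuple(
        LabelingEvent(
            speaker_id=row.speaker_id,
            group=row.group,
            object_id=row.object_id,
            token=row.token,
        )
        for row in df.itertuples(index=False)
    )
    return Corpus(events=events, label_space=label_space, groups=groups)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus to TSV; ``read_corpus`` restores an equal corpus."""
    path = Path(path)
    df = pd.DataFrame(
        [(e.speaker_id, e.group, e.object_id, e.token) for e in corpus.events],
        columns=list(CORPUS_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def _sig6(x: float) -> str:
    return f"{x:.6g}"


def _report_payload(report: Sim1Report | Sim2Report) -> tuple[list[dict], dict]:
    """(CSV rows, JSON document) for a report, with deterministic order."""
    if isinstance(report, Sim1Report):
        rows = [
            {"condition": name, "kl_divergence_bits": _sig6(v)}
            for name, v in report.rows()
        ]
        doc = {
            "kind": "simulation1",
            "parameters": report.params(),
            "values": {
                f"{corr} {grp}": v for (grp, corr), v in sorted(report.values.items())
            },
        }
        return rows, doc
    if isinstance(report, Sim2Report):
        rows = [
            {"label": lab, "posterior": _sig6(p)}
            for lab, p in report.posterior.items()
        ]
        doc = {
            "kind": "simulation2",
            "parameters": report.params(),
            "posterior": dict(report.posterior.items()),
        }
        if report.diagnostics is not None:
            doc["diagnostics"] = json.loads(
                json.dumps(report.diagnostics, default=float)
            )
        return rows, doc
    raise ValidationError(f"cannot serialize report of type {type(report).__name__}")


def write_report(
    report: Sim1Report | Sim2Report,
    path: str | Path,
    format: Literal["csv", "json"] = "csv",
) -> Path:
    """Serialize a report: CSV with 6-significant-digit floats, or JSON at
    full precision (including parameters and any sampler diagnostics)."""
    path = Path(path)
    rows, doc = _report_payload(report)
    if format == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True), encoding="utf-8")
    else:
        raise ValidationError(f"unknown report format {format!r}")
    return path


def write_manifest(path: str | Path, parameters: dict) -> Path:
    """Record everything needed to reproduce a run: parameters, seed(s)
    and package version."""
    path = Path(path)
    doc = {"package": "epilex", "version": __version__, "parameters": parameters}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str),
                    encoding="utf-8")
    return path
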
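"""Run configuration, the end-to-end screen driver, and run manifests.

Configuration precedence is CLI flags > config file > defaults.  Every run
writes a JSON manifest holding the full effective configuration, the seed,
SHA-256 hashes of the inputs, and per-stage record counts, so any number in
an output table can be re-derived from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .io import read_gct, read_intervention_list, read_target_annotations
from .screen import ScreenResult, run_screen
from .types import ValidationError

__all__ = ["RunConfig", "load_config", "run_pipeline", "sha256_file"]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """All tunables of the screen, with the stated defaults."""

    signatures: Optional[str] = None
    interventions: Optional[str] = None
    targets: Optional[str] = None
    cutoff: float = 90.0
    query_size: int = 50
    query_mode: str = "per_cell_line"
    tau_tie_rule: str = "inclusive"
    consolidation_percentiles: tuple[float, float] = (33.0, 67.0)
    de_thresholds: dict = field(
        default_factory=lambda: {
            "kidney": ["pvalue", 0.05],
            "brain": ["pvalue", 0.05],
            "heart": ["adj_pvalue", 0.05],
        }
    )
    logcpm_prior: float = 0.5
    cap: float = 2.0
    seed: int = 0
    include_zero_tally: bool = False

    def validate(self) -> "RunConfig":
        if not -100.0 <= self.cutoff <= 100.0:
            raise ValidationError(f"cutoff {self.cutoff} outside [-100, 100]")
        if self.query_size < 1:
            raise ValidationError("query_size must be >= 1")
        if self.query_mode not in ("per_cell_line", "consensus"):
            raise ValidationError(f"unknown query_mode {self.query_mode!r}")
        if self.tau_tie_rule not in ("inclusive", "exclusive"):
            raise ValidationError(f"unknown tau_tie_rule {self.tau_tie_rule!r}")
        lo, hi = self.consolidation_percentiles
        if not (0 <= lo <= hi <= 100):
            raise ValidationError("consolidation percentiles must be ordered in [0, 100]")
        if self.logcpm_prior < 0:
            raise ValidationError("logcpm_prior must be >= 0")
        if self.cap <= 0:
            raise ValidationError("cap must be positive")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["consolidation_percentiles"] = list(self.consolidation_percentiles)
        return d


def load_config(path: Optional[PathLike] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Overrides with value ``None`` are ignored, so CLI flags that were not
    given fall through to the file (and then to the defaults).
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "consolidation_percentiles" in data:
        data["consolidation_percentiles"] = tuple(data["consolidation_percentiles"])
    return RunConfig(**data).validate()


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: PathLike) -> Path:
    """Execute the screen stages in order and write all outputs + manifest.

    Outputs: ``scores.tsv`` (per-cell-line chain), ``summary_scores.tsv``,
    ``hit_matrix.tsv`` (interventions x compounds, 0/1), ``ranking.tsv``,
    and ``manifest.json``.
    """
    config.validate()
    for name in ("signatures", "interventions", "targets"):
        p = getattr(config, name)
        if p is None:
            raise ValidationError(f"run_pipeline: config.{name} is required")
        if not Path(p).exists():
            raise ValidationError(f"{name} input {p} does not exist")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sigset = read_gct(config.signatures)
    interventions = read_intervention_list(config.interventions)
    annotations = read_target_annotations(config.targets)

    result: ScreenResult = run_screen(
        sigset,
        interventions,
        annotations,
        cutoff=config.cutoff,
        k=config.query_size,
        query_mode=config.query_mode,
        percentiles=config.consolidation_percentiles,
        tau_inclusive=config.tau_tie_rule == "inclusive",
        include_zero=config.include_zero_tally,
    )

    float_fmt = "%.10g"
    result.scores.detail.to_csv(
        out / "scores.tsv", sep="\t", index=False, float_format=float_fmt
    )
    result.scores.summary.to_csv(
        out / "summary_scores.tsv", sep="\t", index=False, float_format=float_fmt
    )
    result.hits.matrix.astype(int).to_csv(out / "hit_matrix.tsv", sep="\t")
    result.ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
    result.hits.provenance.to_csv(
        out / "hit_provenance.tsv", sep="\t", index=False, float_format=float_fmt
    )

    manifest = {
        "tool": {"name": "geroscreen", "version": __version__},
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {
            name: {
                "path": str(getattr(config, name)),
                "sha256": sha256_file(getattr(config, name)),
            }
            for name in ("signatures", "interventions", "targets")
        },
        "stage_counts": result.counts,
        "missing_interventions": result.missing_interventions,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
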
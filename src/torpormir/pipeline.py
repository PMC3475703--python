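"""End-to-end orchestration: stats -> noise floor -> filter -> floor ->
fold -> select -> family summary -> plot, with a run manifest.

The manifest records the tool version, a hash of the effective
configuration, input checksums, and the per-stage accounting, which always
satisfies the partition identity total = kept + excluded.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .containers import ExpressionMatrix
from .differential import differential_table
from .families import plot_family_bars, summarize_families
from .io import (
    file_sha256,
    read_expression_tsv,
    read_family_map,
    write_expression_tsv,
    write_json,
    write_table,
)
from .noise import compute_probe_stats, estimate_noise_floor, plot_cv_mean
from .synthetic import ArrayConfig, generate_array

__all__ = ["RunConfig", "RunManifest", "run_all", "StageError"]

_KNOWN_KEYS = {
    "matrix", "samples", "out_dir", "seed", "simulate",
    "lowess_frac", "grid_size", "slope_tolerance", "min_suffix_fraction",
    "threshold", "baseline_group", "test_group", "family_map", "plots",
}


@dataclass
class RunConfig:
    """Parameters for one end-to-end run.

    Either ``matrix``+``samples`` point to an existing TSV pair, or
    ``simulate`` holds :class:`~torpormir.synthetic.ArrayConfig` overrides
    and the input is generated (seeded by ``seed``).
    """

    out_dir: str = "torpormir_out"
    matrix: str | None = None
    samples: str | None = None
    simulate: dict = field(default_factory=dict)
    seed: int = 0
    lowess_frac: float = 0.3
    grid_size: int = 200
    slope_tolerance: float = 0.1
    min_suffix_fraction: float = 0.25
    threshold: float = 1.25
    baseline_group: str = "ACR"
    test_group: str = "LH"
    family_map: str | None = None
    plots: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict
    accounting: dict
    n_families: int
    families: list
    noise_floor: float
    started: str
    finished: str

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all per-stage outputs.

    Outputs under ``config.out_dir``: matrix/sample TSVs (when simulated),
    noise model JSON, differential record TSV, accounting JSON, family
    summary TSV/JSON, figures, and ``manifest.json``. Deterministic given
    the config and inputs. On failure a ``FAILED`` marker naming the stage
    is left in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stage = "setup"
    try:
        stage = "input"
        checksums = {}
        if config.matrix:
            if not config.samples:
                raise ValueError("matrix given without a sample sheet")
            matrix = read_expression_tsv(config.matrix, config.samples)
            checksums = {
                "matrix": file_sha256(config.matrix),
                "samples": file_sha256(config.samples),
            }
        else:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            if "planted_families" in sim:
                sim["planted_families"] = tuple(
                    (str(f), float(x)) for f, x in sim["planted_families"]
                )
            matrix, truth = generate_array(ArrayConfig(**sim))
            write_expression_tsv(matrix, out / "matrix.tsv", out / "samples.tsv")
            write_json(truth.to_json_dict(), out / "truth.json")
            checksums = {
                "matrix": file_sha256(out / "matrix.tsv"),
                "samples": file_sha256(out / "samples.tsv"),
            }

        stage = "noise"
        model = estimate_noise_floor(
            matrix,
            lowess_frac=config.lowess_frac,
            grid_size=config.grid_size,
            slope_tolerance=config.slope_tolerance,
            min_suffix_fraction=config.min_suffix_fraction,
        )
        model.save(out / "noise_model.json")
        if config.plots:
            plot_cv_mean(compute_probe_stats(matrix), model, out / "cv_mean.png")

        stage = "differential"
        result = differential_table(
            matrix,
            model.noise_floor,
            threshold=config.threshold,
            baseline_group=config.baseline_group,
            test_group=config.test_group,
        )
        write_table(result.records.reset_index(), out / "differential.tsv")
        write_json(result.accounting, out / "accounting.json")

        stage = "families"
        fam_map = read_family_map(config.family_map) if config.family_map else None
        selected = result.records[result.records["selected"]]
        summaries = summarize_families(selected, family_map=fam_map)
        flat = summaries.drop(columns=["members"]) if len(summaries) else summaries
        write_table(flat, out / "families.tsv")
        write_json({"families": summaries.to_dict(orient="records")},
                   out / "families.json")
        if config.plots:
            plot_family_bars(summaries, out / "family_bars.png")

        stage = "manifest"
        manifest = RunManifest(
            version=__version__,
            config_hash=config.config_hash(),
            input_checksums=checksums,
            accounting=result.accounting,
            n_families=int(len(summaries)),
            families=list(summaries["family"]) if len(summaries) else [],
            noise_floor=model.noise_floor,
            started=started,
            finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        write_json(manifest.to_dict(), out / "manifest.json")
        return manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        if isinstance(err, StageError):
            raise
        raise StageError(stage, err) from err
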
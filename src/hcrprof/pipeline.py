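"""End-to-end pipeline: (simulate →) profile → align → metrics, with a run manifest.

A run is driven by a single JSON-serializable :class:`PipelineConfig`.  Every
stage writes its outputs under the configured output directory, and the run
manifest records the config snapshot, package version, per-file sha256
checksums and stage status, so that two runs with identical config and seed
can be verified byte-for-byte from their manifests (integer-grid alignment
keeps every intermediate deterministic).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from . import __version__
from . import io as hio
from .alignment import align_profiles, average_profiles
from .imaging import max_project, extract_profile, normalize_profile
from .metrics import (
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_T_HI,
    DEFAULT_T_LO,
    classify_relation,
)
from .synthetic import PRESETS, SceneConfig, generate_scene

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]

log = logging.getLogger("hcrprof")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


class AlignmentOptions(BaseModel):
    peak_model: str = "gaussian"
    subpixel: bool = False


class MetricsOptions(BaseModel):
    t_hi: float = DEFAULT_T_HI
    t_lo: float = DEFAULT_T_LO
    min_prominence: float = DEFAULT_MIN_PROMINENCE


class PipelineConfig(BaseModel):
    """Declarative description of one pipeline run.

    Exactly one image source must be given: a named preset, an inline
    :class:`~hcrprof.synthetic.SceneConfig`, or a directory of TIFF stacks
    with a line-endpoint table.
    """

    outdir: Path
    preset: str | None = None
    scene: SceneConfig | None = None
    images_dir: Path | None = None
    lines_file: Path | None = None
    reference_channel: str
    query_channels: list[str] = Field(min_length=1)
    linewidth: int = Field(default=1, ge=1)
    alignment: AlignmentOptions = AlignmentOptions()
    metrics: MetricsOptions = MetricsOptions()
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        sources = [self.preset is not None, self.scene is not None, self.images_dir is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of preset, scene or images_dir must be given")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; options: {sorted(PRESETS)}")
        if self.images_dir is not None and self.lines_file is None:
            raise ValueError("lines_file is required when reading images_dir")
        return self


@dataclasses.dataclass
class RunManifest:
    """Record of one pipeline run: config, outputs, checksums and status."""

    config: dict
    version: str
    started: str
    finished: str
    outputs: dict[str, str]  # stage -> path (relative to outdir)
    checksums: dict[str, str]  # relative path -> sha256
    status: str  # 'ok' | 'failed'
    failed_stage: str | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def _setup_logging(outdir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    # timestamp-free format keeps the log reproducible across reruns
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; write intermediates, relations and the manifest.

    Any stage error aborts the run: partial outputs are retained, the
    manifest records the failed stage, and a :class:`PipelineError` naming
    the stage is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir, config.log_level)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    outputs: dict[str, str] = {}
    tracked: list[Path] = []
    stage = "setup"
    try:
        # --- acquire images and lines -----------------------------------
        if config.images_dir is not None:
            stage = "load"
            log.info("reading stacks from %s", config.images_dir)
            stacks = [hio.read_stack(p) for p in sorted(Path(config.images_dir).glob("*.tif"))]
            if not stacks:
                raise ValueError(f"no .tif stacks found in {config.images_dir}")
            lines_by_stack = hio.read_linespecs(config.lines_file)
        else:
            stage = "simulate"
            if config.preset is not None:
                scene = PRESETS[config.preset](seed=config.seed)
            else:
                scene = config.scene.model_copy(update={"seed": config.seed})
            log.info("simulating %d replicates", scene.n_replicates)
            stacks, truth = generate_scene(scene)
            images_dir = outdir / "images"
            images_dir.mkdir(exist_ok=True)
            lines_by_stack = {}
            for stk, line in zip(stacks, truth.lines):
                p = hio.write_stack(stk, images_dir / f"{stk.stack_id}.tif")
                tracked += [p, p.with_suffix(".json")]
                lines_by_stack[stk.stack_id] = [line]
            gt_path = hio.write_ground_truth(truth, outdir / "ground_truth.json")
            lines_path = hio.write_linespecs(lines_by_stack, outdir / "lines.csv")
            tracked += [gt_path, lines_path]
            outputs["simulate"] = "images"

        # --- profiles -----------------------------------------------------
        stage = "profile"
        profiles = []
        for stk in stacks:
            proj = max_project(stk)
            for line in lines_by_stack.get(stk.stack_id, []):
                if config.linewidth != 1 and line.linewidth == 1:
                    line = dataclasses.replace(line, linewidth=config.linewidth)
                profiles.append(normalize_profile(extract_profile(proj, line)))
        if not profiles:
            raise ValueError("no lines matched any stack; check the line table's stack_id values")
        log.info("extracted %d profiles", len(profiles))
        profiles_path = hio.write_profiles(profiles, outdir / "profiles.csv")
        tracked.append(profiles_path)
        outputs["profile"] = "profiles.csv"

        # --- alignment and averaging --------------------------------------
        stage = "align"
        aligned = align_profiles(
            profiles,
            config.reference_channel,
            model=config.alignment.peak_model,
            subpixel=config.alignment.subpixel,
        )
        avg = average_profiles(aligned)
        avg_path = hio.write_average(avg, outdir / "average.csv")
        fits_path = hio.write_json(hio.fits_to_dict(aligned.fits), outdir / "fits.json")
        tracked += [avg_path, fits_path]
        outputs["align"] = "average.csv"
        log.info(
            "aligned %d profiles on a %d-point grid", len(aligned.profiles), avg.grid.size
        )

        # --- domain metrics -----------------------------------------------
        stage = "metrics"
        rel_dir = outdir / "relations"
        rel_dir.mkdir(exist_ok=True)
        for query in config.query_channels:
            rel = classify_relation(
                avg,
                config.reference_channel,
                query,
                t_hi=config.metrics.t_hi,
                t_lo=config.metrics.t_lo,
                min_prominence=config.metrics.min_prominence,
            )
            p = hio.write_json(
                rel.to_dict(), rel_dir / f"{query}_vs_{config.reference_channel}.json"
            )
            tracked.append(p)
            log.info("%s vs %s: %s (overlap %.3f)", query, config.reference_channel,
                     rel.call, rel.overlap_coefficient)
        outputs["metrics"] = "relations"

        status, failed_stage, error = "ok", None, None
    except Exception as exc:  # noqa: BLE001 — manifest must record any stage failure
        status, failed_stage, error = "failed", stage, str(exc)
        log.error("stage %s failed: %s", stage, exc)
    finally:
        log.removeHandler(handler)
        handler.close()

    checksums = {
        str(p.relative_to(outdir)): hio.sha256_file(p) for p in sorted(set(tracked))
    }
    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        version=__version__,
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=outputs,
        checksums=checksums,
        status=status,
        failed_stage=failed_stage,
        error=error,
    )
    manifest.write(outdir / "manifest.json")
    if status == "failed":
        raise PipelineError(failed_stage, error)
    return manifest
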
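"""End-to-end orchestration: simulate -> discover -> lock -> validate -> report.

A run is described by a single YAML config; every stage writes its artifacts
plus a manifest entry (input checksums, seed, package version), so a rerun
with the same config reproduces byte-identical outputs and every number in
the report is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .discovery import (
    LockedCutoff,
    ProfileConfig,
    cv_significance_profile,
    find_peaks,
    lock_cutoff,
)
from .errors import PipelineError
from .io import (
    read_clinical,
    read_matrix,
    read_profile,
    survival_from_clinical,
    write_profile,
)
from .simulate import preset, simulate_cohort, write_cohort
from .validate import classify_cases, mutation_enrichment, validate_os

log = logging.getLogger("survcut.pipeline")

STAGES = ("simulate", "discover", "lock", "validate", "report")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: Path
    seed: int = 0
    preset: str = "training-like"
    n: int | None = None
    gene: str = "BAALC"
    adverse_side: str = "below"
    stages: tuple[str, ...] = STAGES
    n_reps: int = 1000
    alpha: float = 0.05
    split_fraction: float = 0.5
    min_support: float = 0.20
    min_high: int = 2
    percentile: float | None = None   # force a percentile instead of peak choice

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d["out_dir"] = Path(d.get("out_dir", "survcut_run"))
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Each stage fails fast with a :class:`PipelineError` naming the stage;
    partial outputs of the failed stage are removed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "preset": cfg.preset,
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    for stage in cfg.stages:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
        written: list[Path] = []
        try:
            if stage == "simulate":
                cohort = simulate_cohort(preset(cfg.preset, n=cfg.n), seed=cfg.seed)
                paths = write_cohort(cohort, out)
                written = list(paths.values())
                artifacts.update(paths)
            elif stage == "discover":
                expr = read_matrix(_require(artifacts, out, "expression", "expression.tsv", stage))
                clin = read_clinical(_require(artifacts, out, "clinical", "clinical.csv", stage))
                s = survival_from_clinical(clin, "os")
                profile = cv_significance_profile(
                    expr.loc[cfg.gene].to_numpy(float),
                    s,
                    ProfileConfig(
                        n_reps=cfg.n_reps,
                        alpha=cfg.alpha,
                        split_fraction=cfg.split_fraction,
                        seed=cfg.seed,
                    ),
                )
                ppath = out / "profile.tsv"
                write_profile(profile, ppath)
                written = [ppath]
                artifacts["profile"] = ppath
            elif stage == "lock":
                expr = read_matrix(_require(artifacts, out, "expression", "expression.tsv", stage))
                profile = read_profile(
                    _require(artifacts, out, "profile", "profile.tsv", stage),
                    n_reps=cfg.n_reps,
                    alpha=cfg.alpha,
                )
                if cfg.percentile is not None:
                    chosen = cfg.percentile
                else:
                    peaks = find_peaks(profile)
                    chosen = profile.argmax_percentile() if peaks else None
                if chosen is None:
                    raise PipelineError("lock: no peak found in the profile")
                cut = lock_cutoff(
                    expr.loc[cfg.gene].to_numpy(float),
                    gene=cfg.gene,
                    percentile=chosen,
                    adverse_side=cfg.adverse_side,
                    provenance={"preset": cfg.preset, "seed": cfg.seed},
                )
                cpath = out / "cutoff.json"
                cut.to_json(cpath)
                written = [cpath]
                artifacts["cutoff"] = cpath
            elif stage == "validate":
                expr = read_matrix(_require(artifacts, out, "expression", "expression.tsv", stage))
                clin = read_clinical(_require(artifacts, out, "clinical", "clinical.csv", stage))
                cut = LockedCutoff.from_json(
                    _require(artifacts, out, "cutoff", "cutoff.json", stage)
                )
                labels = classify_cases(expr, cut)
                report = validate_os(
                    labels,
                    survival_from_clinical(clin, "os"),
                    cut.adverse_side,
                    gene=cut.gene,
                    threshold=cut.threshold,
                    alpha=cfg.alpha,
                )
                mut_cols = [c for c in ("npm1", "cebpa_dm", "flt3_itd") if c in clin]
                enrich = (
                    [r.__dict__ for r in mutation_enrichment(labels, clin[mut_cols])]
                    if mut_cols
                    else []
                )
                vpath = out / "validation.json"
                payload = report.to_dict()
                payload["enrichment"] = enrich
                vpath.write_text(json.dumps(payload, indent=1, default=float))
                written = [vpath]
                artifacts["validation"] = vpath
            elif stage == "report":
                vpath = _require(artifacts, out, "validation", "validation.json", stage)
                rpath = out / "report.txt"
                rpath.write_text(render_report(json.loads(vpath.read_text())))
                written = [rpath]
                artifacts["report"] = rpath
        except PipelineError:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(f"{stage}: {exc}") from exc

        manifest["stages"][stage] = {
            "artifacts": {p.name: _sha256(p) for p in written},
            "seed": cfg.seed,
        }
        log.info("stage %s done: %s", stage, ", ".join(p.name for p in written))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _require(artifacts: dict, out: Path, key: str, fname: str, stage: str) -> Path:
    path = artifacts.get(key, out / fname)
    if not Path(path).exists():
        raise PipelineError(f"{stage}: required input {fname} is missing")
    return Path(path)


def render_report(validation: dict) -> str:
    """Human-readable per-gene summary table (deterministic text)."""
    if not validation:
        log.warning("empty artifact set: rendering empty report")
        return "(no validation artifacts)\n"
    lines = [
        "gene      endpoint  n_low  n_high  HR      95% CI            p(1-sided)  result",
        "-" * 84,
    ]
    rows = validation if isinstance(validation, list) else [validation]
    for v in rows:
        ci = f"{v['ci_lower']:.3f}-{v['ci_upper']:.3f}"
        lines.append(
            f"{v['gene'] or '-':<9} {v['endpoint']:<8} {v['n_low']:>5}  {v['n_high']:>6}"
            f"  {v['hr']:<7.3f} {ci:<17} {v['p_one_sided']:<11.4g} "
            + ("pass" if v["passed"] else "fail")
        )
        for e in v.get("enrichment", []):
            lines.append(
                f"  {e['mutation']:<12} low {e['mutant_low']}/{e['n_low']}"
                f"  high {e['mutant_high']}/{e['n_high']}"
                f"  Fisher p = {e['p_two_sided']:.4g}"
            )
    return "\n".join(lines) + "\n"
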
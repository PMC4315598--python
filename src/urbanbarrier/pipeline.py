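"""End-to-end pipeline orchestration.

``run_pipeline`` executes the six canonical stages in dependency order —
simulate (or load), pairs, permtest, matched, neighborhoods, trend — and
writes one artifact file per stage plus a run manifest (config digest,
seed, package versions, completed stages; wall-clock timings are recorded
under a separate key so the result artifacts are reproducible
byte-for-byte from the same config and seed).

All stochastic stages derive child seeds from the master seed by fixed
offsets: the simulator uses ``seed`` and the permutation test uses
``seed + 1`` (both reduced modulo 2^31).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .barrier_test import match_equidistant_pairs, paired_t_test, permutation_test
from .genotype_io import MicrosatDataset, read_genotype_table, write_genotype_table
from .neighborhood import (
    INDEX_NAMES,
    longitudinal_trend,
    neighborhood_indices,
    select_radius,
)
from .pairwise import build_pair_table
from .synthetic_city import SimulationConfig, simulate

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31
_PERM_SEED_OFFSET = 1

STAGES = ("simulate", "pairs", "permtest", "matched", "neighborhoods", "trend")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for the CLI exit message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``input`` (a wide-dialect genotype CSV) or ``sim`` (a
    simulator configuration) provides the data.  The remaining fields hold
    the analysis constants: 10,000 permutations, 1 m matching tolerance,
    candidate radii 100..250 m in 25 m steps, minimum neighborhood size
    10, rarefaction to 10 individuals, and a 5% levels-off threshold.
    """

    outdir: Path
    input: Optional[Path] = None
    sim: Optional[SimulationConfig] = None
    n_perm: int = 10_000
    tolerance_m: float = 1.0
    radii: tuple = (100, 125, 150, 175, 200, 225, 250)
    min_n: int = 10
    rarefaction_g: int = 10
    levels_off_threshold: float = 0.05
    neighborhood_year: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.input is None) == (self.sim is None):
            raise ValueError("provide exactly one of 'input' or 'sim'")
        if self.input is not None:
            self.input = Path(self.input)
            if not self.input.exists():
                raise FileNotFoundError(self.input)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: Optional[Path] = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        if outdir is not None:
            raw["outdir"] = outdir
        raw.setdefault("outdir", "urbanbarrier_out")
        if "radii" in raw:
            raw["radii"] = tuple(raw["radii"])
        return cls(sim=sim, **raw)

    def digest(self) -> str:
        # outdir is where results land, not part of what was computed
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir"
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    Any stage failure raises :class:`PipelineStageError` naming the stage.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - every stage error aborts the run
            logger.error("[%s] failed: %s", name, e)
            raise PipelineStageError(name, e) from e
        timings[name] = time.perf_counter() - t0
        completed.append(name)
        logger.info("[%s] done in %.2fs", name, timings[name])
        return result

    state: dict = {}

    def stage_simulate():
        if cfg.sim is not None:
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed % _SEED_MOD)
            ds = simulate(sim_cfg)
        else:
            ds = read_genotype_table(cfg.input, dialect="wide")
        path = outdir / "data.csv"
        write_genotype_table(ds, path)
        artifacts["data"] = path.name
        state["ds"] = ds

    def stage_pairs():
        pt = build_pair_table(state["ds"])
        path = outdir / "pairs.csv"
        pt.to_csv(path)
        artifacts["pairs"] = path.name
        state["pairs"] = pt

    def stage_permtest():
        if cfg.n_perm < 1:
            raise ValueError(
                f"n_perm must be >= 1 (permutation test precondition), got {cfg.n_perm}"
            )
        res = permutation_test(
            state["ds"], n_perm=cfg.n_perm,
            seed=(cfg.seed + _PERM_SEED_OFFSET) % _SEED_MOD,
        )
        path = outdir / "permtest.json"
        _write_json(path, res.to_dict())
        artifacts["permtest"] = path.name
        state["permtest"] = res

    def stage_matched():
        m = match_equidistant_pairs(state["pairs"], tolerance=cfg.tolerance_m)
        t = paired_t_test(m)
        m.to_csv(outdir / "matched.csv")
        _write_json(
            outdir / "matched_test.json",
            {
                "t_stat": t.t_stat,
                "df": t.df,
                "p_two_sided": t.p_two_sided,
                "mean_difference": t.mean_difference,
                "n_couples": t.n_couples,
                "tolerance_m": cfg.tolerance_m,
            },
        )
        artifacts["matched"] = "matched.csv"
        artifacts["matched_test"] = "matched_test.json"

    def stage_neighborhoods():
        scan = select_radius(
            state["ds"], radii=cfg.radii, min_n=cfg.min_n,
            threshold=cfg.levels_off_threshold, year=cfg.neighborhood_year,
        )
        _write_json(
            outdir / "radius_scan.json",
            {
                "radii": scan.radii,
                "valid_counts": scan.valid_counts,
                "selected": scan.selected,
                "threshold": scan.threshold,
            },
        )
        indices = neighborhood_indices(
            state["ds"], radius=scan.selected, min_n=cfg.min_n,
            rarefaction_g=cfg.rarefaction_g, year=cfg.neighborhood_year,
        )
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "sample_id": i.sample_id,
                    "n": i.n_neighbors,
                    "ho": i.ho,
                    "he": i.he,
                    "f_is": i.f_is,
                    "ar": i.ar,
                    "valid": i.valid,
                }
                for i in indices
            ]
        ).to_csv(outdir / "indices.csv", index=False)
        artifacts["radius_scan"] = "radius_scan.json"
        artifacts["indices"] = "indices.csv"
        state["indices"] = indices

    def stage_trend():
        trends = {}
        for name in INDEX_NAMES:
            fit = longitudinal_trend(state["indices"], state["ds"], name)
            trends[name] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "f_stat": fit.f_stat,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        _write_json(outdir / "trends.json", trends)
        artifacts["trends"] = "trends.json"

    run_stage("simulate", stage_simulate)
    run_stage("pairs", stage_pairs)
    run_stage("permtest", stage_permtest)
    run_stage("matched", stage_matched)
    run_stage("neighborhoods", stage_neighborhoods)
    run_stage("trend", stage_trend)

    import numpy, pandas, scipy, statsmodels

    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stages_completed": completed,
        "artifacts": artifacts,
        "versions": {
            "urbanbarrier": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
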
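"""End-to-end run: (simulate | read) -> standardize -> LMM ladder -> curves
-> capacity -> trade-off report, with a reproducibility manifest.

Every stage writes a plain CSV into the output directory; the manifest
records the configuration, the seed and a checksum per file so that a rerun
with the same configuration can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as curves_mod
from . import lmm as lmm_mod
from . import metrics as metrics_mod
from .simulate import (AT_CODE, CSV_COLUMNS, SEX_CODE, SimulationParams,
                       TT_CENTER, default_params, simulate_dataset,
                       write_observations)

log = logging.getLogger(__name__)

STAGES = ("input", "standardize", "fixed_effects", "ladder", "curves",
          "capacity", "tradeoff")


class InputError(ValueError):
    """Malformed observation table."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one of ``input_path`` (an observation CSV) or ``sim_params``
    (generate the data in-run) must be given. ``fraction`` is the breadth
    threshold, ``t_cut`` the optimum-temperature inclusion cut.
    """

    output_dir: str | Path = "thermperf_run"
    input_path: str | Path | None = None
    sim_params: SimulationParams | None = None
    seed: int = 0
    fraction: float = 0.8
    t_cut: float = 32.0
    df_method: str = "residual"
    ladder_models: tuple[int, ...] = tuple(range(1, 9))

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim_params is None):
            raise ValueError("exactly one of input_path / sim_params "
                             "must be set")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie strictly in (0, 1)")


def read_observations(path) -> pd.DataFrame:
    """Read and validate the canonical observation CSV.

    Rows with a missing Ucrit are dropped (count logged); malformed headers,
    non-numeric fields, nonpositive performances and unknown sex or
    acclimation codes are hard errors.
    """
    table = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"missing columns in {path}: {sorted(missing)}")
    n0 = len(table)
    table = table.dropna(subset=["ucrit_bl_s"]).copy()
    if n0 - len(table):
        log.warning("dropped %d rows with missing ucrit_bl_s", n0 - len(table))
    try:
        table["ucrit_bl_s"] = pd.to_numeric(table["ucrit_bl_s"])
        table["test_temp_c"] = pd.to_numeric(table["test_temp_c"])
        table["accl_temp_c"] = pd.to_numeric(table["accl_temp_c"])
    except (ValueError, TypeError) as exc:
        raise InputError(f"non-numeric field: {exc}") from None
    if (table["ucrit_bl_s"] <= 0).any():
        raise InputError("ucrit_bl_s must be positive (BL s^-1)")
    bad_accl = set(table["accl_temp_c"].unique()) - set(AT_CODE)
    if bad_accl:
        raise InputError(f"unknown acclimation temperatures {sorted(bad_accl)}; "
                         f"valid: {sorted(AT_CODE)}")
    sex = table["sex"].astype(str).str.lower()
    bad_sex = set(sex.unique()) - set(SEX_CODE)
    if bad_sex:
        raise InputError(f"unknown sex codes {sorted(bad_sex)}; "
                         f"valid: {sorted(SEX_CODE)}")
    table["sex"] = sex
    table["fish_id"] = table["fish_id"].astype(str)
    table["tt"] = table["test_temp_c"] - TT_CENTER
    return table.reset_index(drop=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["output_dir"] = str(echo["output_dir"])
    if echo["input_path"] is not None:
        echo["input_path"] = str(echo["input_path"])
    if echo["sim_params"] is not None:
        echo["sim_params"]["re_corr"] = np.asarray(
            echo["sim_params"]["re_corr"]).tolist()
        for k in ("test_temps", "accl_temps"):
            echo["sim_params"][k] = list(echo["sim_params"][k])
    echo["ladder_models"] = list(echo["ladder_models"])
    return echo


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write the reports plus a manifest.

    Returns a dict with the in-memory stage outputs. Deterministic stages
    are bit-reproducible for a fixed configuration and seed; a stage failure
    raises :class:`StageError` naming the stage, with the outputs of earlier
    stages retained on disk.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    written: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    stage = "input"
    try:
        if config.sim_params is not None:
            params = config.sim_params.replace(seed=config.seed)
            obs = simulate_dataset(params)
            write_observations(obs, outdir / "observations.csv")
            written.append(outdir / "observations.csv")
        else:
            obs = read_observations(config.input_path)
        outputs["observations"] = obs

        stage = "standardize"
        obs = lmm_mod.standardize_response(obs)
        outputs["observations"] = obs

        stage = "fixed_effects"
        fit1 = lmm_mod.fit_lmm(lmm_mod.build_design(obs, 1), method="ML")
        fe = lmm_mod.fixed_effect_table(fit1, df_method=config.df_method)
        outputs["fixed_effects"] = fe
        _write("fixed_effects.csv", fe)

        stage = "ladder"
        ladder, fits = lmm_mod.run_ladder(obs, config.ladder_models)
        outputs["ladder"] = ladder
        outputs["ladder_fits"] = fits
        _write("ladder.csv", ladder)
        lrts = lmm_mod.ladder_lrt_table(fits)
        outputs["ladder_lrts"] = lrts
        _write("ladder_lrts.csv", lrts)

        stage = "curves"
        summaries = curves_mod.curve_summaries(obs, fraction=config.fraction,
                                               t_cut=config.t_cut)
        included, exclusions = curves_mod.filter_individuals(
            summaries, t_cut=config.t_cut)
        outputs["curve_summaries"] = summaries
        outputs["exclusion_report"] = exclusions
        _write("curve_summaries.csv", summaries)
        _write("curve_exclusions.csv", exclusions)

        stage = "capacity"
        capacity = metrics_mod.build_capacity_table(obs)
        outputs["capacity"] = capacity
        _write("capacity.csv", capacity)

        stage = "tradeoff"
        tradeoff = metrics_mod.tradeoff_report(summaries, capacity)
        outputs["tradeoff"] = tradeoff
        _write("tradeoff.csv", tradeoff)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config": _config_echo(config),
        "curve_scale": "raw_bl_s",
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    outputs["manifest"] = manifest
    return outputs


def simulate_config(seed: int = 0, output_dir="thermperf_run",
                    params: SimulationParams | None = None,
                    **kwargs) -> RunConfig:
    """Convenience constructor for a simulate-mode run."""
    return RunConfig(output_dir=output_dir, seed=seed,
                     sim_params=params or default_params(seed), **kwargs)
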
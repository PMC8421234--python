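"""End-to-end analysis run: cohort in, fitted NTCP model and reports out.

``run_pipeline`` chains the stages of the cohort analysis — univariate
screening, collinearity clustering, forward selection, final logistic fit,
Hosmer-Lemeshow calibration, tolerance-dose table, and volume-stratified
NTCP curves — and writes every artifact plus a manifest (config snapshot,
package version, input checksum, stage timings, warnings) so a run can be
audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_cohort, write_cohort
from .logistic import LogisticModel
from .ntcp import NTCPModel, hosmer_lemeshow
from .selection import (
    STANDARD_FACTORS,
    correlation_clusters,
    forward_select,
    univariate_screen,
    univariate_table,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Configuration of one analysis run (defaults = study conditions)."""

    cohort_path: str | None = None
    out_dir: str = "thyntcp_run"
    alpha_beta: float = 3.0
    dvh_bin_width: float = 0.1
    vx_levels: tuple[int, ...] = (10, 20, 30, 40, 45, 50, 60, 70)
    rho_threshold: float = 0.8
    p_enter: float = 0.05
    hl_groups: int = 10
    td_levels: tuple[float, ...] = (0.05, 0.10)
    curve_volumes: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0)
    screen_factors: tuple[str, ...] = STANDARD_FACTORS
    seed: int = 0
    simulate_n: int | None = None  # simulate a cohort instead of reading one

    def __post_init__(self):
        if not 0 < self.p_enter < 1:
            raise ValueError("p_enter must be in (0,1)")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0,1]")
        if self.hl_groups < 3:
            raise ValueError("hl_groups must be >= 3")
        if self.dvh_bin_width <= 0:
            raise ValueError("dvh_bin_width must be > 0")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        for k in ("vx_levels", "td_levels", "curve_volumes", "screen_factors"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        return cls(**data)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    univariate: pd.DataFrame
    clusters: list
    selection: object
    model: NTCPModel
    calibration: object
    td_table: pd.DataFrame
    curves: pd.DataFrame
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run screen -> cluster -> forward -> fit -> calibration -> TD -> curves.

    All artifacts are written under ``config.out_dir``; a failing stage
    raises :class:`StageError` naming the stage, with earlier artifacts
    preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    caught: list[str] = []
    manifest: dict = {
        "package": "thyntcp",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "inputs": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.ctx = warnings.catch_warnings(record=True)
                self.log = self.ctx.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                self.ctx.__exit__(None, None, None)
                caught.extend(f"{name}: {w.message}" for w in self.log)
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    _write_manifest()
                    raise StageError(f"stage '{name}' failed: {exc}") from exc
        return _Timer()

    def _write_manifest():
        manifest["stage_timings_s"] = {k: round(v, 4) for k, v in timings.items()}
        manifest["warnings"] = caught
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    with stage("load_cohort"):
        if config.simulate_n is not None:
            from .simulate import CohortSimConfig, simulate_cohort

            cohort = simulate_cohort(
                CohortSimConfig(n_patients=config.simulate_n, seed=config.seed))
            write_cohort(cohort, out / "cohort.csv")
            manifest["inputs"]["cohort"] = {"simulated_n": config.simulate_n,
                                            "seed": config.seed}
        else:
            if config.cohort_path is None:
                raise ValueError("either cohort_path or simulate_n is required")
            cohort = read_cohort(config.cohort_path)
            manifest["inputs"]["cohort"] = {"path": str(config.cohort_path),
                                            "sha256": _sha256(config.cohort_path)}

    with stage("univariate_screen"):
        uni = univariate_screen(cohort, config.screen_factors)
        uni_tab = univariate_table(uni)
        uni_tab.to_csv(out / "univariate.csv")

    with stage("correlation_clusters"):
        # cluster the univariately significant factors; every cluster (incl.
        # singletons) contributes its representative to the candidate set
        significant = [r.factor for r in uni if r.ok and r.p_value < config.p_enter]
        clusters = correlation_clusters(cohort, significant,
                                        rho_threshold=config.rho_threshold,
                                        univariate=uni) if significant else []
        candidates = [c.representative for c in clusters]
        (out / "clusters.json").write_text(json.dumps(
            [{"members": list(c.members), "representative": c.representative}
             for c in clusters], indent=2))

    with stage("forward_selection"):
        sel = forward_select(cohort, candidates, p_enter=config.p_enter)
        (out / "selection.json").write_text(json.dumps(
            {"candidates": candidates, "selected": list(sel.selected),
             "trace": sel.trace}, indent=2, default=float))

    with stage("final_model"):
        # the NTCP equation is the two-covariate dose/volume logistic model;
        # the selection report documents whether the data agree with that form
        final = ["dmean_gy", "volume_cc"]
        if set(sel.selected) != set(final):
            warnings.warn(
                f"forward selection chose {list(sel.selected)}; the NTCP "
                f"equation is nevertheless fitted on {final}")
        fit = LogisticModel.from_dataframe(cohort, "outcome_12m", final).fit()
        model = NTCPModel.from_results(fit)
        model.to_json(out / "ntcp_model.json")
        (out / "model_summary.txt").write_text(fit.summary() + "\n")

    with stage("calibration"):
        cal = hosmer_lemeshow(fit.predict(), cohort["outcome_12m"].to_numpy(),
                              n_groups=config.hl_groups)
        cal.table.to_csv(out / "calibration_groups.csv", index=False)
        (out / "calibration.json").write_text(json.dumps(
            {"chi_square": cal.chi_square, "df": cal.df, "p_value": cal.p_value},
            indent=2))

    with stage("tolerance_doses"):
        median_vol = float(np.median(cohort["volume_cc"]))
        td = pd.DataFrame(
            [{"p": p, "volume_cc": median_vol,
              "td_gy": model.tolerance_dose(median_vol, p)}
             for p in config.td_levels])
        td.to_csv(out / "tolerance_doses.csv", index=False)

    with stage("curves"):
        frames = []
        for v in config.curve_volumes:
            c = model.curve(v)
            c.insert(0, "volume_cc", v)
            frames.append(c)
        curves = pd.concat(frames, ignore_index=True)
        curves.to_csv(out / "ntcp_curves.csv", index=False)

    _write_manifest()
    return PipelineResult(cohort=cohort, univariate=uni_tab, clusters=clusters,
                          selection=sel, model=model, calibration=cal,
                          td_table=td, curves=curves, manifest=manifest)
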
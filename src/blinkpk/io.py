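"""Configuration, delimited-text I/O, and the umbrella pipeline.

All artifacts are UTF-8 comma-delimited text with '.' decimals and a header
row; the first line of every file is a comment stamping the package version,
the master seed and a hash of the resolved configuration, so a rerun with
the same seed is byte-identical and traceable.

Sweeps travel in long format (sweep_id, stim_time_s, true_ce, sample_idx,
amplitude_uv); sedation tables as (time_s, arass, ce_ug_ml); trajectories as
(time_s, cp_ug_ml, ce_ug_ml).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import endpoints as _endpoints
from . import features as _features
from . import mlr as _mlr
from . import pkstat as _pkstat
from . import preprocess as _preprocess
from . import synth as _synth
from .pkpd import DEFAULT_DT_S, DEFAULT_REMIFENTANIL_CE_NG_ML
from .synth import (
    DEFAULT_POPULATION,
    PopulationConfig,
    SedationRecord,
    SimulatedSession,
    Sweep,
    session_rng,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "write_sweeps",
    "read_sweeps",
    "write_sedation",
    "read_sedation",
    "write_trajectory",
    "run_pipeline",
    "build_feature_table",
]

log = logging.getLogger("blinkpk")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for a full pipeline run.

    Defaults are the documented study conditions: 3.3 mL/kg/h of 1% propofol,
    ke0 0.456 1/min, 0.1-s integration step, the cohort-calibrated population,
    Pk selection threshold 0.700, and remifentanil as a constant 2.5 ng/mL
    covariate.
    """

    seed: int = 0
    n_patients: int = 8
    population: PopulationConfig = DEFAULT_POPULATION
    pk_dt_s: float = DEFAULT_DT_S
    pk_ke0_per_min: float = 0.456
    protocol_infusion_ml_kg_h: float = 3.3
    protocol_propofol_mg_per_ml: float = 10.0
    remifentanil_ce_ng_ml: float = DEFAULT_REMIFENTANIL_CE_NG_ML
    welch: _features.WelchConfig = _features.WelchConfig()
    band_hz: tuple[float, float] = (30.0, 120.0)
    pk_threshold: float = 0.700
    r_threshold: float = 0.500
    presence_k: float = _endpoints.DEFAULT_PRESENCE_K
    mlr_preset: str = "auto-select"  # or "published"
    out_dir: str = "blinkpk_out"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # hash the science, not the paths
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


_NESTED_FIELDS = {"population": PopulationConfig, "welch": _features.WelchConfig}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys are rejected before any computation.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    for name, cls in _NESTED_FIELDS.items():
        if name in data and isinstance(data[name], dict):
            sub_known = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(data[name]) - sub_known
            if sub_unknown:
                raise ValueError(
                    f"unknown {name} configuration key(s): {sorted(sub_unknown)}")
            data[name] = cls(**data[name])
    if "band_hz" in data:
        data["band_hz"] = tuple(data["band_hz"])
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _stamp(cfg: PipelineConfig | None) -> str:
    if cfg is None:
        return "# blinkpk artifact\n"
    return f"# blinkpk seed={cfg.seed} config_hash={cfg.config_hash()}\n"


def _write_frame(frame: pd.DataFrame, path: Path, cfg: PipelineConfig | None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_stamp(cfg))
        # %.17g guarantees an exact float64 round-trip through text
        frame.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def _read_frame(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the default C float parser is (slightly) lossy
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_sweeps(sweeps, path: str | Path, cfg: PipelineConfig | None = None) -> None:
    """Write sweeps in long format (exact decimal round-trip via repr)."""
    rows = []
    for sid, s in enumerate(sweeps):
        rows.append(pd.DataFrame({
            "sweep_id": sid,
            "stim_time_s": s.stim_time_s,
            "true_ce": s.true_ce,
            "sample_idx": np.arange(len(s.samples)),
            "amplitude_uv": s.samples,
        }))
    _write_frame(pd.concat(rows, ignore_index=True), Path(path), cfg)


def read_sweeps(path: str | Path) -> list[Sweep]:
    """Read a long-format sweep file back into Sweep objects.

    Raises
    ------
    ValueError
        If any sweep has the wrong geometry (truncated or corrupt file).
    """
    frame = _read_frame(path)
    sweeps = []
    for sid, grp in frame.groupby("sweep_id", sort=True):
        n = len(grp)
        if n != _synth.SWEEP_SAMPLES:
            raise ValueError(
                f"sweep {sid} has {n} samples, expected {_synth.SWEEP_SAMPLES} "
                "(truncated or corrupt file)"
            )
        grp = grp.sort_values("sample_idx")
        sweeps.append(Sweep(
            stim_time_s=float(grp["stim_time_s"].iloc[0]),
            fs_hz=_synth.SWEEP_FS_HZ,
            samples=grp["amplitude_uv"].to_numpy(dtype=float),
            true_ce=float(grp["true_ce"].iloc[0]),
        ))
    return sweeps


def write_sedation(records, path: str | Path, cfg: PipelineConfig | None = None) -> None:
    frame = pd.DataFrame({
        "time_s": [r.time_s for r in records],
        "arass": [r.arass for r in records],
        "ce_ug_ml": [r.ce for r in records],
    })
    _write_frame(frame, Path(path), cfg)


def read_sedation(path: str | Path) -> list[SedationRecord]:
    frame = _read_frame(path)
    return [SedationRecord(time_s=float(r.time_s), arass=int(r.arass),
                           ce=float(r.ce_ug_ml))
            for r in frame.itertuples()]


def write_trajectory(traj, path: str | Path, cfg: PipelineConfig | None = None) -> None:
    _write_frame(traj.to_frame(), Path(path), cfg)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: PipelineConfig) -> list[SimulatedSession]:
    """Draw and simulate ``n_patients`` sessions.

    Each patient gets an independent RNG stream derived from (seed, index),
    so adding patients never changes earlier patients' data.
    """
    sessions = []
    for i in range(cfg.n_patients):
        t0 = time.perf_counter()
        rng = session_rng(cfg.seed, i)
        profile = _synth.draw_patient(rng, cfg.population)
        session = _synth.simulate_session(
            profile, rng, dt_s=cfg.pk_dt_s, ke0_per_min=cfg.pk_ke0_per_min)
        sessions.append(session)
        log.info("simulate patient=%d sweeps=%d elapsed=%.2fs",
                 i, len(session.sweeps), time.perf_counter() - t0)
    return sessions


def build_feature_table(session: SimulatedSession, patient_id: str,
                        cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Feature rows for one session: one row per (averaged stimulus, window).

    Averaged records whose window is silent (an all-zero, noise-free window
    after component abolition) are skipped.
    """
    rows = []
    for j, avg in _preprocess.sliding_averages(session.sweeps):
        t1, t2 = _preprocess.extract_windows(avg)
        rec = session.sedation[j]
        for win in (t1, t2):
            try:
                fv = _features.window_features(win, cfg.welch, band=cfg.band_hz)
            except ValueError:
                continue  # silent or empty-spectrum window
            rows.append({
                "patient_id": patient_id,
                "stim_time_s": avg.stim_time_s,
                "ce_ug_ml": avg.true_ce,
                "arass": rec.arass,
                "window": win.window_id,
                **fv.as_dict(),
            })
    return pd.DataFrame(rows)


def _wide_predictors(features_frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long feature table to window-suffixed predictor columns."""
    keys = ["patient_id", "stim_time_s", "ce_ug_ml", "arass"]
    wide = features_frame.pivot_table(
        index=keys, columns="window",
        values=list(_features.FEATURE_COLUMNS), sort=False)
    wide.columns = [f"{feat}_{win}" for feat, win in wide.columns]
    return wide.reset_index().dropna()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute simulate → features → Pk → MLR → endpoints → report.

    Writes features.csv, pk_table.csv, model.json, endpoints.csv and
    summary.txt (plus the resolved config) under ``cfg.out_dir`` and returns
    the artifact paths.  Any stage failure is re-raised with the stage and
    patient identity attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        _stamp(cfg) + yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))

    sessions = simulate_cohort(cfg)

    frames, records = [], []
    for i, session in enumerate(sessions):
        pid = f"p{i:03d}"
        try:
            frames.append(build_feature_table(session, pid, cfg))
            records.append(_endpoints.detect_endpoints(
                session, k=cfg.presence_k, patient_id=pid))
        except ValueError as exc:
            raise RuntimeError(f"stage=features/endpoints patient={pid}: {exc}") from exc
    features_frame = pd.concat(frames, ignore_index=True)
    _write_frame(features_frame, out / "features.csv", cfg)
    log.info("features rows=%d", len(features_frame))

    pk_frame = _pkstat.pk_table(features_frame, _features.FEATURE_COLUMNS)
    _write_frame(pk_frame, out / "pk_table.csv", cfg)

    wide = _wide_predictors(features_frame)
    if cfg.mlr_preset == "published":
        predictors = [p for p in _mlr.PUBLISHED_LOGIT_PREDICTORS if p in wide.columns]
    else:
        sel = _mlr.select_features(pk_frame, cfg.pk_threshold, cfg.r_threshold)
        # model building uses the features passing BOTH screens (Pk and |R|)
        sel = sel[sel["r_selected"]] if sel["r_selected"].any() else sel
        predictors = ["ce_ug_ml"] + [
            f"{row.feature}_{row.window}" for row in sel.itertuples()]
    predictors = _mlr.prune_collinear(wide, predictors)
    # synthetic features can separate small cohorts perfectly; drop the
    # offending predictor and refit rather than abort the whole run.  A
    # cohort too small to support any fit records that fact in the model
    # artifact instead of failing the run.
    model = diag = None
    fit_error = None
    while True:
        try:
            model = _mlr.fit_multinomial(wide, predictors)
            diag = _mlr.fit_diagnostics(model, wide)
            break
        except _mlr.SeparationError as exc:
            if exc.predictor not in predictors:
                fit_error = str(exc)
                break
            log.warning("fit-mlr: dropping separating predictor %r", exc.predictor)
            predictors = [p for p in predictors if p != exc.predictor]
        except ValueError as exc:
            fit_error = str(exc)
            break
    if model is not None and diag is not None:
        model_doc = {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "reference_class": model.reference_class,
            "classes": list(model.classes),
            "predictors": list(model.predictor_names),
            "coefficients": model.coefficients.tolist(),
            "log_likelihood": model.log_likelihood,
            "n_obs": model.n_obs,
            "overall_chi2": diag.overall_chi2,
            "overall_df": diag.overall_df,
            "overall_p": diag.overall_p,
            "nagelkerke_r2": diag.nagelkerke_r2,
            "accuracy": diag.accuracy,
            "lr_tests": {k: list(v) for k, v in diag.lr_tests.items()},
        }
    else:
        log.warning("fit-mlr: no model fitted: %s", fit_error)
        model_doc = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                     "error": fit_error}
    (out / "model.json").write_text(json.dumps(model_doc, indent=2) + "\n")

    endpoints_frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    _write_frame(endpoints_frame, out / "endpoints.csv", cfg)
    if len(records) >= 3:
        body = _endpoints.summarize_cohort(records).to_text()
    else:
        body = (f"Cohort summary unavailable: n = {len(records)} < 3; "
                "see endpoints.csv for per-patient endpoints.")
    (out / "summary.txt").write_text(_stamp(cfg) + body + "\n")

    return {name: out / name for name in
            ("config.yaml", "features.csv", "pk_table.csv", "model.json",
             "endpoints.csv", "summary.txt")}
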
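"""End-to-end orchestration: ECG file → CDG result; cohort CSV → report.

These are the library entry points behind the ``cdg compute`` and
``cdg evaluate`` commands.  Every report embeds the configuration hash so
identical inputs and configuration produce identical reports (modulo the
timestamp field).
"""

from __future__ import annotations

import json
import logging
import os
import time
from datetime import datetime, timezone

from .classifier import CDGClassifier
from .config import RunConfig
from .errors import CdgError
from .heterogeneity import compute_indices
from .model import CardiodynamicsModel, LearningParams

logger = logging.getLogger(__name__)


class StageError(CdgError):
    """Wraps a stage failure with the stage name for CLI reporting."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage
        self.cause = exc


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except CdgError as exc:
                raise StageError(getattr(exc, "stage", name), exc) from exc
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %s: %.3f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def _load_classifier(cfg: RunConfig) -> CDGClassifier:
    if cfg.classifier.model == "paper-2023":
        return CDGClassifier.paper_2023()
    return CDGClassifier.from_json(cfg.classifier.model)


def run_subject(ecg_path: str, config: RunConfig | None = None,
                out_dir: str | None = None, fmt: str = "csv",
                fs: float = 1000.0) -> dict:
    """Full per-subject chain; returns the result dict and writes artifacts.

    Artifacts (when ``out_dir`` is given): heterogeneity-indices CSV, CDG
    trajectory CSV, a 3-D CDG plot (PNG) and the result JSON.
    """
    cfg = config or RunConfig()

    from .io import FilterSpec, denoise, read_ecg
    from .vcg import KorsMatrix, kors_transform
    from .fiducials import detect_r_peaks, extract_stt_loops, locate_beat_fiducials

    rec = _stage("signal_io")(read_ecg)(ecg_path, format=fmt, fs=fs)
    p = cfg.preprocess
    spec = FilterSpec(p.notch_hz, p.bandpass_lo_hz, p.bandpass_hi_hz,
                      p.order, p.notch_q)
    clean = _stage("signal_io")(denoise)(rec, spec)
    matrix = (KorsMatrix.from_csv(cfg.vcg.matrix_file)
              if cfg.vcg.matrix_file else None)
    v = _stage("vcg_transform")(kors_transform)(clean, matrix)
    peaks = _stage("fiducials")(detect_r_peaks)(v, use_lead=cfg.fiducials.detector_lead)
    fids = _stage("fiducials")(locate_beat_fiducials)(v, peaks)
    loops = _stage("fiducials")(extract_stt_loops)(v, fids, L=cfg.fiducials.loop_points)
    if loops.n_beats < cfg.fiducials.min_beats:
        raise StageError("fiducials", CdgError(
            f"only {loops.n_beats} usable beats; need {cfg.fiducials.min_beats}"))

    r = cfg.rbf
    params = LearningParams(gain_a=r.gain_a, gamma=r.gamma, sigma=r.sigma,
                            epochs=r.epochs)
    model = CardiodynamicsModel(loops, spacing=r.spacing,
                                width_factor=r.width_factor, params=params,
                                classifier=_load_classifier(cfg),
                                subject_id=rec.subject_id)
    res = _stage("cardiodynamics")(model.fit)()
    import numpy as np

    grid = None
    if cfg.thi.grid_max is not None:
        grid = np.arange(1, cfg.thi.grid_max + 1)
    idx = _stage("heterogeneity")(compute_indices)(
        res.trajectory, step_k=cfg.shi.step_k, theiler_w=cfg.shi.theiler,
        lambda_grid=grid, spectrum_mode=cfg.thi.spectrum_mode)
    score = model.classifier.cdg_value(idx)
    call = model.classifier.classify(score)

    result = {
        "subject_id": rec.subject_id,
        "shi": idx.shi,
        "thi": idx.thi,
        "n_points": idx.n_points,
        "step_k": idx.step_k,
        "cdg_value": score,
        "call": call,
        "n_beats": loops.n_beats,
        "loop_points": loops.L,
        "classifier": model.classifier.version,
        "config_hash": cfg.hash(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        sid = rec.subject_id or "subject"
        import pandas as pd

        pd.DataFrame([{
            "subject_id": sid, "shi": idx.shi, "thi": idx.thi,
            "n_points": idx.n_points, "step_k": idx.step_k,
        }]).to_csv(os.path.join(out_dir, f"{sid}_indices.csv"), index=False)
        res.trajectory.to_frame().to_csv(os.path.join(out_dir, f"{sid}_cdg.csv"))
        ax = res.plot()
        ax.figure.savefig(os.path.join(out_dir, f"{sid}_cdg.png"), dpi=100)
        import matplotlib.pyplot as plt

        plt.close(ax.figure)
        with open(os.path.join(out_dir, f"{sid}_result.json"), "w") as fh:
            json.dump(result, fh, indent=1)
    return result


def run_cohort(cohort_csv: str, config: RunConfig | None = None,
               standard: int | None = None, out_dir: str | None = None,
               seed: int = 0) -> dict:
    """Evaluate CDG calls in a cohort table against one reference standard."""
    cfg = config or RunConfig()
    std = standard if standard is not None else cfg.evaluate.standard

    from .cohort import evaluate_cohort, read_cohort
    from .errors import TrainingError

    df = _stage("cohort_eval")(read_cohort)(cohort_csv)
    try:
        report = evaluate_cohort(df, standard=std, ci=cfg.evaluate.ci, seed=seed)
    except TrainingError:
        # single-class cohort: metrics without AUC
        from .cohort import (CohortRecord, ReferenceStandard, confusion,
                             label_cad, metrics)

        ref = ReferenceStandard.by_number(std)
        truths, calls = [], []
        for _, row in df.iterrows():
            rec = CohortRecord(str(row["subject_id"]), row["stenosis_band"],
                               float(row["ctffr"]), bool(row["occluded"]))
            truths.append(label_cad(rec, ref))
            calls.append("positive" if float(row["cdg_value"]) >= 0 else "negative")
        summ = metrics(*confusion(calls, truths))
        report = summ.to_dict()
        report.update({"standard": std, "n": summ.n,
                       "n_positive": sum(t == "positive" for t in truths),
                       "auc": None, "spearman_rho": None, "spearman_p": None})
    report["config_hash"] = cfg.hash()
    report["timestamp"] = datetime.now(timezone.utc).isoformat()
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, f"evaluation_std{std}.json"), "w") as fh:
            json.dump(report, fh, indent=1)
        import pandas as pd

        pd.DataFrame([report]).to_csv(
            os.path.join(out_dir, f"evaluation_std{std}.csv"), index=False)
    return report
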
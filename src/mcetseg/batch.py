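"""Batch sweeps over image sets and estimator grids.

One row per (image, estimator config) with the threshold, the two class
means and all six quality metrics; a summary table averages each metric per
config across the image set.  Rows for recognised-but-unsupported
configurations (the lognormal baseline) carry status ``"unsupported"`` and
empty numeric cells, so the standard 22-row grid keeps its shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimatorSpec
from .exceptions import McetsegError, UndefinedMetricError
from .mcet import segment
from .metrics import evaluate_segmentation

#: Fixed column order of the per-image table.
COLUMNS = [
    "image", "method", "param", "status",
    "t_raw", "mu1", "mu2",
    "IU", "RC", "IRD", "JI", "F", "ACC",
]

METRIC_COLUMNS = ["IU", "RC", "IRD", "JI", "F", "ACC"]


@dataclass(frozen=True)
class BatchEntry:
    """One image (with optional ground truth) of a batch."""

    name: str
    image: np.ndarray
    truth: np.ndarray | None = None


def _run_one(entry: BatchEntry, spec: EstimatorSpec) -> dict:
    row = {
        "image": entry.name,
        "method": spec.method,
        "param": spec.param,
        "status": "ok",
        "t_raw": None, "mu1": None, "mu2": None,
        "IU": None, "RC": None, "IRD": None,
        "JI": None, "F": None, "ACC": None,
    }
    if not spec.supported:
        row["status"] = "unsupported"
        return row
    try:
        mask, result = segment(entry.image, spec)
        report = evaluate_segmentation(
            entry.image, mask, result.mu1, result.mu2, result.t_raw,
            truth=entry.truth,
        )
    except UndefinedMetricError as exc:
        row["status"] = f"undefined metric: {exc}"
        return row
    except McetsegError as exc:
        row["status"] = f"error: {exc}"
        return row
    row.update(t_raw=result.t_raw, mu1=result.mu1, mu2=result.mu2)
    row.update(report.as_dict())
    return row


def run_batch(
    entries: list[BatchEntry],
    specs: list[EstimatorSpec],
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Segment and score every (image, config) pair.

    ``n_jobs > 1`` parallelises over images with joblib; rows are assembled
    in the same deterministic order either way, so results are independent
    of the worker count.
    """
    if not entries:
        raise ValueError("empty image set")
    jobs = [(entry, spec) for entry in entries for spec in specs]
    if n_jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_one)(entry, spec) for entry, spec in jobs
        )
    else:
        rows = [_run_one(entry, spec) for entry, spec in jobs]
    return pd.DataFrame(rows, columns=COLUMNS)


def summarize(per_image: pd.DataFrame) -> pd.DataFrame:
    """Per-config averages of each metric across the image set.

    One row per (method, param) in first-appearance order, averaging only
    rows with status ``"ok"``; ``n_images`` counts them.  The best config
    per metric is flagged in ``best_for``.
    """
    df = per_image.copy()
    df["config"] = df.apply(
        lambda r: r["method"] if pd.isna(r["param"]) or r["param"] is None
        else f"{r['method']}:{r['param']:g}",
        axis=1,
    )
    order = df["config"].drop_duplicates().tolist()
    ok = df[df["status"] == "ok"]
    rows = []
    for config in order:
        sub = ok[ok["config"] == config]
        row = {"config": config, "n_images": len(sub)}
        for col in METRIC_COLUMNS:
            values = pd.to_numeric(sub[col], errors="coerce").dropna()
            row[col] = float(values.mean()) if len(values) else None
        rows.append(row)
    summary = pd.DataFrame(rows)
    best = {}
    for col in METRIC_COLUMNS:
        series = pd.to_numeric(summary[col], errors="coerce")
        if series.notna().any():
            best[col] = summary.loc[series.idxmax(), "config"]
    summary["best_for"] = summary["config"].map(
        lambda c: ",".join(sorted(m for m, cfg in best.items() if cfg == c)) or ""
    )
    return summary
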
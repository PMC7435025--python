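"""Comparison statistics for perfusion estimates against a reference.

Implements the evaluation battery used to compare mapping methods:
summary statistics of the estimates (mean, SD, median), error metrics
against a per-voxel reference (mean signed error, RMSE, MAE, Pearson
correlation), paired t tests on per-voxel absolute errors, signed-error
profiles binned by reference perfusion (10-unit intervals), and
perfusion histograms.  The reference is normally the multigrid fit,
mirroring its role as the silver standard for both training and testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodComparison",
    "DegenerateInputError",
    "error_metrics",
    "paired_accuracy_test",
    "binned_error_profile",
    "perfusion_histogram",
    "compare_all",
    "save_report",
]

_ABS_TOL = 1e-9


class DegenerateInputError(ValueError):
    """Statistic undefined for this input (e.g. zero-variance differences)."""


@dataclass(frozen=True)
class MethodComparison:
    """One method's estimates summarised against a common reference."""

    method: str
    reference: str
    n_voxels: int
    mean: float
    sd: float
    median: float
    mean_error: float
    rmse: float
    mae: float
    pearson_r: float

    def __post_init__(self) -> None:
        # power-mean inequality and |mean| <= mean(|.|); violations can only
        # come from implementation bugs, so fail loudly
        if self.mae > self.rmse + _ABS_TOL:
            raise AssertionError(f"MAE {self.mae} exceeds RMSE {self.rmse}")
        if abs(self.mean_error) > self.rmse + _ABS_TOL:
            raise AssertionError("RMSE below |mean error|")
        if not -1.0 - _ABS_TOL <= self.pearson_r <= 1.0 + _ABS_TOL:
            raise AssertionError("correlation outside [-1, 1]")


def _check_pair(estimates, reference):
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("estimates and reference must be equal-length 1-D, nonempty")
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
        raise ValueError("inputs must be finite")
    return est, ref


def error_metrics(estimates, reference, method: str = "method",
                  reference_name: str = "reference") -> MethodComparison:
    """Summary and error statistics of ``estimates`` against ``reference``.

    mean_error = mean(est - ref); rmse = sqrt(mean((est - ref)^2));
    mae = mean(|est - ref|); pearson_r is the sample correlation (both
    vectors need nonzero variance).
    """
    est, ref = _check_pair(estimates, reference)
    err = est - ref
    if est.std() == 0 or ref.std() == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    r = float(stats.pearsonr(est, ref).statistic)
    return MethodComparison(
        method=method,
        reference=reference_name,
        n_voxels=est.size,
        mean=float(est.mean()),
        sd=float(est.std(ddof=1)),
        median=float(np.median(est)),
        mean_error=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.mean(np.abs(err))),
        pearson_r=r,
    )


def paired_accuracy_test(abs_err_a, abs_err_b) -> tuple[float, float]:
    """Two-sided paired t test on per-voxel absolute-error differences.

    Returns (t, p).  The pairing is per voxel: both error vectors must
    come from the same voxels in the same order.
    """
    a, b = _check_pair(abs_err_a, abs_err_b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise DegenerateInputError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def binned_error_profile(estimates, reference, bin_width: float = 10.0) -> pd.DataFrame:
    """Mean signed error per half-open reference bin ``[b, b + width)``.

    Columns: ``bin_left``, ``bin_center``, ``n_voxels``, ``mean_error``.
    Empty bins are omitted.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    est, ref = _check_pair(estimates, reference)
    left = np.floor(ref / bin_width) * bin_width
    df = pd.DataFrame({"bin_left": left, "error": est - ref})
    g = df.groupby("bin_left", sort=True)["error"].agg(["size", "mean"]).reset_index()
    return pd.DataFrame({
        "bin_left": g["bin_left"],
        "bin_center": g["bin_left"] + bin_width / 2.0,
        "n_voxels": g["size"].astype(int),
        "mean_error": g["mean"],
    })


def perfusion_histogram(values, bin_width: float = 10.0) -> dict:
    """Histogram of perfusion values plus their mean and median.

    Returns ``{"table": DataFrame(bin_left, bin_center, count),
    "mean": float, "median": float}``; bins are half-open ``[b, b+w)``.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a nonempty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    left = np.floor(v / bin_width) * bin_width
    uniq, counts = np.unique(left, return_counts=True)
    table = pd.DataFrame({
        "bin_left": uniq,
        "bin_center": uniq + bin_width / 2.0,
        "count": counts.astype(int),
    })
    return {"table": table, "mean": float(v.mean()), "median": float(np.median(v))}


def compare_all(reference, methods: dict, reference_name: str = "multigrid",
                bin_width: float = 10.0) -> dict:
    """Full method comparison against one reference voxel vector.

    Parameters
    ----------
    reference : 1-D array of reference perfusion values (one per voxel).
    methods : dict name -> 1-D estimate array on the identical voxels.

    Returns a dict with a summary ``table`` (one MethodComparison row per
    method, the reference's own row first), pairwise paired-t ``p_values``
    on absolute errors, and per-method binned error ``profiles``.
    """
    ref = np.asarray(reference, dtype=float)
    for name, est in methods.items():
        if np.asarray(est).shape != ref.shape:
            raise ValueError(f"method {name!r} voxel set does not match the reference")

    rows = []
    # reference-vs-itself row: zero errors by definition, r = 1
    rows.append(MethodComparison(
        method=reference_name, reference=reference_name, n_voxels=ref.size,
        mean=float(ref.mean()), sd=float(ref.std(ddof=1)), median=float(np.median(ref)),
        mean_error=0.0, rmse=0.0, mae=0.0, pearson_r=1.0,
    ))
    profiles = {}
    abs_errors = {}
    for name, est in methods.items():
        rows.append(error_metrics(est, ref, method=name, reference_name=reference_name))
        profiles[name] = binned_error_profile(est, ref, bin_width)
        abs_errors[name] = np.abs(np.asarray(est, dtype=float) - ref)

    p_values = {}
    names = list(methods)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                t, p = paired_accuracy_test(abs_errors[a], abs_errors[b])
            except DegenerateInputError:
                t, p = np.nan, np.nan
            p_values[f"{a}_vs_{b}"] = {"t": t, "p": p}

    table = pd.DataFrame([asdict(r) for r in rows])
    return {"table": table, "p_values": p_values, "profiles": profiles}


def save_report(report: dict, csv_path=None, json_path=None) -> None:
    """Serialize a :func:`compare_all` report as CSV and/or JSON."""
    if csv_path is not None:
        report["table"].to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "table": report["table"].to_dict(orient="records"),
            "p_values": report["p_values"],
            "profiles": {
                k: v.to_dict(orient="records") for k, v in report["profiles"].items()
            },
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
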
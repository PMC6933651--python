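"""Reading and writing the canonical long-format delimited text files.

The canonical on-disk form of a dataset is a delimited table with a
header row, integer ``time`` and ``case`` columns and one numeric column
per marker.  Fit results are serialised as a directory of delimited
files with all cluster indices 1-based.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    BlockKey,
    DataValidationError,
    FitResult,
    TimeSeriesDataset,
)

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _sep_for(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_long_table(
    path: str,
    marker_columns: Optional[Sequence[str]] = None,
    time_col: str = "time",
    case_col: str = "case",
    delimiter: Optional[str] = None,
) -> TimeSeriesDataset:
    """Load a long-format delimited file into a TimeSeriesDataset.

    Rows are grouped into (time, case) blocks; (t, d) combinations absent
    from the file become empty blocks.  Non-finite marker values are
    rejected with their (1-based, data) row numbers.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path, delimiter), float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError(f"{path}: file is empty") from exc
    for col in (time_col, case_col):
        if col not in df.columns:
            raise DataValidationError(f"{path}: required column '{col}' is missing")
    if marker_columns is None:
        marker_columns = [c for c in df.columns if c not in (time_col, case_col)]
    else:
        missing = [c for c in marker_columns if c not in df.columns]
        if missing:
            raise DataValidationError(f"{path}: marker columns not found: {missing}")
    if not marker_columns:
        raise DataValidationError(f"{path}: no marker columns")

    markers = df[list(marker_columns)].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(markers.to_numpy(dtype=float))
    if bad.any():
        rows = (np.nonzero(bad.any(axis=1))[0] + 1).tolist()
        raise DataValidationError(
            f"{path}: non-finite or non-numeric marker values at data rows {rows[:10]}"
        )
    times = pd.to_numeric(df[time_col], errors="coerce")
    cases = pd.to_numeric(df[case_col], errors="coerce")
    if times.isna().any() or cases.isna().any():
        raise DataValidationError(f"{path}: non-numeric time/case values")

    blocks: Dict[BlockKey, np.ndarray] = {}
    values = markers.to_numpy(dtype=float)
    key = pd.DataFrame({"t": times.astype(int), "d": cases.astype(int)})
    for (t, d), idx in key.groupby(["t", "d"]).groups.items():
        blocks[(int(t), int(d))] = values[np.asarray(idx)]
    return TimeSeriesDataset(blocks, marker_names=list(marker_columns))


def write_long_table(
    data: TimeSeriesDataset, path: str, delimiter: Optional[str] = None
) -> None:
    """Serialise a dataset in the canonical long format (inverse of read)."""
    frames = []
    for t, d, Y in data.iter_blocks():
        if Y.shape[0] == 0:
            continue
        df = pd.DataFrame(Y, columns=data.marker_names)
        df.insert(0, "case", d)
        df.insert(0, "time", t)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep=_sep_for(path, delimiter), index=False, float_format=_FLOAT_FMT)


def write_results(result: FitResult, out_dir: str, marker_names: Optional[Sequence[str]] = None) -> List[str]:
    """Write a fitted model to a directory of delimited files.

    Emits cluster_means.csv, cluster_covariances.csv (long),
    mixture_proportions.csv, persistency.csv, assignments.csv,
    loglik_trace.csv and config.yaml.  Cluster indices are 1-based.
    """
    os.makedirs(out_dir, exist_ok=True)
    mu = result.params.mu
    L, K = mu.shape
    names = list(marker_names) if marker_names else [f"marker_{j + 1}" for j in range(K)]

    written = []

    def _save(name: str, df: pd.DataFrame) -> None:
        p = os.path.join(out_dir, name)
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)

    means = pd.DataFrame(mu, columns=names)
    means.insert(0, "cluster", np.arange(1, L + 1))
    _save("cluster_means.csv", means)

    cov_rows = [
        {"cluster": l + 1, "row_marker": names[i], "col_marker": names[j],
         "value": result.params.sigma[l, i, j]}
        for l in range(L) for i in range(K) for j in range(K)
    ]
    _save("cluster_covariances.csv", pd.DataFrame(cov_rows))

    T, D, _ = result.trajectory.pi.shape
    pi_rows = [
        {"time": t + 1, "case": d + 1, "cluster": l + 1,
         "pi": result.trajectory.pi[t, d, l]}
        for t in range(T) for d in range(D) for l in range(L)
    ]
    _save("mixture_proportions.csv", pd.DataFrame(pi_rows))

    a_rows = [
        {"time": t + 1, "case": d + 1, "alpha": result.trajectory.alpha[t, d]}
        for t in range(T) for d in range(D)
    ]
    _save("persistency.csv", pd.DataFrame(a_rows))

    assign_frames = []
    for (t, d), lab in sorted(result.assignments.labels.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if lab.size == 0:
            continue
        assign_frames.append(pd.DataFrame({
            "time": t, "case": d, "cell": np.arange(1, lab.size + 1),
            "cluster": lab + 1,
        }))
    _save("assignments.csv", pd.concat(assign_frames, ignore_index=True))

    _save("loglik_trace.csv", pd.DataFrame({
        "iteration": np.arange(1, len(result.loglik_trace) + 1),
        "loglik": result.loglik_trace,
    }))

    cfg: Dict[str, object] = {}
    if result.hyper is not None:
        cfg.update({
            "L": int(result.hyper.n_clusters),
            "tau": float(result.hyper.tau),
            "nu": float(result.hyper.nu) if result.hyper.nu is not None else None,
            "lambda": np.asarray(result.hyper.lam).tolist() if result.hyper.lam is not None else None,
            "alpha_init": float(result.hyper.alpha_init),
            "pi0": np.asarray(result.hyper.pi0).tolist() if result.hyper.pi0 is not None else None,
        })
    if result.config is not None:
        cfg.update({
            "n_iter": int(result.config.n_iter),
            "burn_in": int(result.config.burn_in),
            "rel_tol": float(result.config.rel_tol),
            "seed": result.config.seed,
            "init_method": result.config.init_method,
        })
    p = os.path.join(out_dir, "config.yaml")
    with open(p, "w") as fh:
        yaml.safe_dump(cfg, fh)
    written.append(p)
    return written


def read_persistency(out_dir: str) -> np.ndarray:
    """Load the (T, D) persistency table written by :func:`write_results`."""
    df = pd.read_csv(os.path.join(out_dir, "persistency.csv"), float_precision="round_trip")
    T, D = int(df["time"].max()), int(df["case"].max())
    alpha = np.full((T, D), np.nan)
    for _, r in df.iterrows():
        alpha[int(r["time"]) - 1, int(r["case"]) - 1] = r["alpha"]
    if np.isnan(alpha).any():
        raise DataValidationError(f"{out_dir}/persistency.csv: incomplete (time, case) grid")
    return alpha


def read_model_config(path: str) -> Dict[str, object]:
    """Read a model config (YAML/JSON) into TimeSeriesGaussianMixture kwargs.

    Recognised keys: L, tau, nu, lambda_scale, alpha_init, n_iter,
    burn_in, rel_tol, seed, init_method (plus asinh_cofactor and
    threshold_quantile, returned untouched for the CLI layer).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataValidationError(f"{path}: config must be a mapping")
    mapping = {
        "L": "n_clusters",
        "tau": "tau",
        "nu": "nu",
        "lambda_scale": "lambda_",
        "alpha_init": "alpha_init",
        "n_iter": "n_iter",
        "burn_in": "burn_in",
        "rel_tol": "rel_tol",
        "seed": "random_state",
        "init_method": "init_method",
    }
    out: Dict[str, object] = {}
    for key, val in raw.items():
        if key in mapping:
            out[mapping[key]] = val
        elif key in ("asinh_cofactor", "threshold_quantile"):
            out[key] = val
        else:
            raise DataValidationError(f"{path}: unknown config key '{key}'")
    return out
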
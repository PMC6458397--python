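"""Summaries of replicate traces and tabular / graphical export.

The central container is a tidy "trace table": one row per
(arm, trial index, quantity) holding the across-replicate mean and standard
error, mirroring the familiar presentation of simulated learning curves
(panel a: response probabilities; panel b: the underlying memory values).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TRACE_COLUMNS", "summarize", "write_csv", "read_csv", "plot_traces"]

TRACE_COLUMNS = ["arm", "trial_index", "quantity", "mean", "stderr", "n_replicates"]


def summarize(
    replicate_traces: np.ndarray | Sequence[np.ndarray],
    labels: Sequence[str],
    arm: str = "",
) -> pd.DataFrame:
    """Per-trial mean and standard error across replicates.

    ``replicate_traces`` is an array of shape (n_replicates, n_rows,
    n_quantities), or a sequence of equally shaped (n_rows, n_quantities)
    arrays; ragged trial counts are an error.  The standard error is the
    sample standard deviation (ddof=1) divided by sqrt(n); it is 0 for a
    single replicate.
    """
    if not isinstance(replicate_traces, np.ndarray):
        shapes = {np.asarray(t).shape for t in replicate_traces}
        if len(shapes) > 1:
            raise ValueError(f"replicates have ragged trial counts: {sorted(shapes)}")
        replicate_traces = np.asarray(list(replicate_traces), dtype=float)
    if replicate_traces.ndim != 3:
        raise ValueError("expected an array of shape (replicates, trials, quantities)")
    n_rep, n_rows, n_q = replicate_traces.shape
    if n_rep < 1:
        raise ValueError("need at least one replicate")
    if len(labels) != n_q:
        raise ValueError("label count does not match number of traced quantities")
    means = replicate_traces.mean(axis=0)
    if n_rep > 1:
        stderr = replicate_traces.std(axis=0, ddof=1) / np.sqrt(n_rep)
    else:
        stderr = np.zeros_like(means)
    rows = []
    for qi, label in enumerate(labels):
        for t in range(n_rows):
            rows.append((arm, t, label, means[t, qi], stderr[t, qi], n_rep))
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_csv(table: pd.DataFrame, path) -> None:
    """Write a trace table as CSV with a deterministic layout.

    Fixed header ``arm,trial_index,quantity,mean,stderr,n_replicates``, rows
    sorted by (arm, quantity, trial index), floats at 12 significant digits
    (lossless round-trip at that precision, diff-friendly files).
    """
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table is missing column(s) {missing}")
    out = (
        table[TRACE_COLUMNS]
        .sort_values(["arm", "quantity", "trial_index"], kind="mergesort")
        .reset_index(drop=True)
    )
    out.to_csv(path, index=False, float_format="%.12g")


def read_csv(path) -> pd.DataFrame:
    """Read back a trace table written by :func:`write_csv`."""
    return pd.read_csv(
        path,
        dtype={
            "arm": str,
            "trial_index": np.int64,
            "quantity": str,
            "mean": float,
            "stderr": float,
            "n_replicates": np.int64,
        },
        keep_default_na=False,
        na_values=["nan", ""],
    )


def plot_traces(table: pd.DataFrame, path, title: str | None = None):
    """Render a two-panel learning-curve figure (best effort).

    Panel (a): response-probability quantities (labels starting with ``p``);
    panel (b): memory values (labels starting with ``v:`` or ``w:``).  Arms
    are distinguished by line style.  Never affects numeric outputs; an empty
    table produces a warning and no file.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        warnings.warn("empty trace table: no figure written")
        return None
    prob = table[table["quantity"].str.startswith(("p:", "p_", "ann:"))]
    mem = table[table["quantity"].str.startswith(("v:", "w:"))]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    styles = ["-", "--", ":", "-."]
    arm_style = {a: styles[i % len(styles)] for i, a in enumerate(sorted(table["arm"].unique()))}
    for ax, sub, ylab, panel in (
        (axes[0], prob, "probability", "(a)"),
        (axes[1], mem, "memory value", "(b)"),
    ):
        for (arm, q), grp in sub.groupby(["arm", "quantity"], sort=True):
            grp = grp.sort_values("trial_index")
            name = f"{q} [{arm}]" if arm else q
            ax.plot(grp["trial_index"], grp["mean"], arm_style.get(arm, "-"), label=name)
        ax.set_xlabel("learning opportunities")
        ax.set_ylabel(ylab)
        ax.set_title(panel, loc="left")
        if len(sub):
            ax.legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150, metadata={"Software": "sociallearn"})
    plt.close(fig)
    return path
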
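"""Calibration and calling performance metrics.

* Calibration tables compare predicted base qualities to the empirical
  quality per predicted-score row; the frequency-weighted squared error
  (FWSE) summarises a table as ``sum_rows freq * (predicted - empirical)^2``
  over well-populated rows.
* ROC curves/AUC rank sites by a score (typically the LLR) against a truth
  labelling, grouping tied scores into single steps.
* ``compare_runs`` intersects call tables from repeated runs and classifies
  each minor allele into mutation classes (CpG-context C>T, C>T, T>C, C>A,
  A>C, G>C, other), folding reverse-complement pairs together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import ObservationBatch
from .recalibrate import empirical_phred

DEFAULT_MIN_ROW_COUNT = 100


@dataclass
class CalibrationTable:
    """Per predicted-score row: base count, error count, empirical phred and
    relative frequency; sparse rows (below ``min_row_count``) are masked."""

    table: pd.DataFrame             # predicted, bases, errors, empirical, frequency, masked
    min_row_count: int = DEFAULT_MIN_ROW_COUNT

    def unmasked(self) -> pd.DataFrame:
        return self.table[~self.table["masked"]]


def calibration_table(predicted_qualities, is_error=None,
                      min_row_count: int = DEFAULT_MIN_ROW_COUNT) -> CalibrationTable:
    """Tabulate empirical vs predicted quality.

    Accepts an :class:`ObservationBatch` (using its qualities and mismatch
    flags) or two parallel arrays of predicted phred scores and error
    indicators.  Relative frequencies are normalised over unmasked rows.
    """
    if isinstance(predicted_qualities, ObservationBatch):
        batch = predicted_qualities
        q = np.asarray(batch.qual, dtype=np.int64)
        err = np.asarray(batch.mismatch, dtype=bool)
    else:
        q = np.asarray(predicted_qualities, dtype=np.int64)
        err = np.asarray(is_error, dtype=bool)
    if q.size == 0:
        raise ValueError("empty input")
    hi = int(q.max()) + 1
    bases = np.bincount(q, minlength=hi)
    errors = np.bincount(q[err], minlength=hi)
    rows = np.flatnonzero(bases)
    emp = empirical_phred(errors[rows], bases[rows])
    masked = bases[rows] < min_row_count
    freq = np.zeros(rows.shape[0])
    tot = bases[rows][~masked].sum()
    if tot > 0:
        freq[~masked] = bases[rows][~masked] / tot
    df = pd.DataFrame({
        "predicted": rows, "bases": bases[rows], "errors": errors[rows],
        "empirical": np.atleast_1d(emp), "frequency": freq, "masked": masked,
    })
    return CalibrationTable(df, min_row_count=min_row_count)


def fwse(table: CalibrationTable) -> float:
    """Frequency-weighted squared error between predicted and empirical
    quality over unmasked rows; invariant to uniform count scaling."""
    df = table.unmasked()
    if len(df) == 0:
        raise ValueError("no unmasked rows")
    f = df["frequency"].to_numpy()
    f = f / f.sum()
    return float(np.sum(f * (df["predicted"].to_numpy(dtype=float)
                             - df["empirical"].to_numpy()) ** 2))


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, truth_labels) -> RocResult:
    """ROC over every distinct score threshold (ties grouped into one step);
    AUC by the trapezoid rule, i.e. ties earn half credit."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth_labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    npos = int(y.sum())
    nneg = int((~y).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s = s[order]
    y = y[order]
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.empty(0, int)
    idx = np.append(distinct, s.size - 1)
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(~y)[idx]
    tpr = np.concatenate([[0.0], tp / npos])
    fpr = np.concatenate([[0.0], fp / nneg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=s[idx], fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Multi-run comparison and mutation classes
# ---------------------------------------------------------------------------

#: reverse-complement-folded substitution classes
_CLASS_FOLD = {
    ("C", "T"): "CT", ("G", "A"): "CT",
    ("T", "C"): "TC", ("A", "G"): "TC",
    ("C", "A"): "CA", ("G", "T"): "CA",
    ("A", "C"): "AC", ("T", "G"): "AC",
    ("G", "C"): "GC", ("C", "G"): "GC",
}


def mutation_class(major: str, minor: str, reference: str, position: int) -> str:
    """Mutation class of a (major -> minor) substitution at a 1-based
    position; C>T at a CpG dinucleotide (or G>A at its complement) is its
    own class."""
    pair = (major, minor)
    cls = _CLASS_FOLD.get(pair, "other")
    if cls == "CT":
        i = position - 1
        if pair == ("C", "T") and i + 1 < len(reference) and reference[i + 1] == "G":
            return "CpG"
        if pair == ("G", "A") and i - 1 >= 0 and reference[i - 1] == "C":
            return "CpG"
    return cls


def compare_runs(run_calls: Mapping[str, Sequence], reference: str) -> pd.DataFrame:
    """Intersect call lists from >= 2 runs on a common reference.

    ``run_calls`` maps run name to a list of :class:`~segreg.caller.SiteCall`.
    Returns one row per (position, minor allele) with the number of runs it
    was detected in, per-run LLR and ML MAF, and the mutation class.
    """
    if len(run_calls) < 2:
        raise ValueError("need at least two runs to compare")
    names = list(run_calls)
    keys: dict = {}
    for name in names:
        for c in run_calls[name]:
            if c.position > len(reference):
                raise ValueError(
                    f"call at {c.position} beyond the reference length — "
                    "runs were not made against a common reference")
            keys.setdefault((c.position, c.major_allele, c.minor_allele), {})[name] = c
    rows = []
    for (pos, major, minor), per_run in sorted(keys.items()):
        row = {"position": pos, "major": major, "minor": minor,
               "n_runs": len(per_run),
               "class": mutation_class(major, minor, reference, pos)}
        for name in names:
            c = per_run.get(name)
            row[f"llr_{name}"] = c.llr if c else np.nan
            row[f"maf_{name}"] = c.ml_maf if c else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optional plots
# ---------------------------------------------------------------------------

def plot_calibration(tables: Mapping[str, CalibrationTable], path) -> None:
    """Empirical-vs-predicted scatter for one or more calibration tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    hi = 0
    for name, t in tables.items():
        df = t.unmasked()
        ax.scatter(df["predicted"], df["empirical"], s=12, label=name)
        hi = max(hi, df["predicted"].max(), df["empirical"].max())
    ax.plot([0, hi], [0, hi], "k--", lw=0.8)
    ax.set_xlabel("predicted phred")
    ax.set_ylabel("empirical phred")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(rocs: Mapping[str, RocResult], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in rocs.items():
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
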
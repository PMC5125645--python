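"""Accuracy scoring against reference structures and batch benchmarking.

Base-pair level scoring uses exact pair identity (no slip tolerance):

    Sn  = TP / (TP + FN)        sensitivity
    PPV = TP / (TP + FP)        positive predictive value
    Accuracy = (Sn + PPV) / 2

TP counts predicted pairs present in the reference, FP predicted pairs
absent from it, FN reference pairs missed.  When a denominator is zero the
metric is 1 only in the doubly-empty case (nothing to predict, nothing
predicted) and 0 otherwise; the replicate means printed by ``benchmark`` may
be fractional, and the formulas are applied to those means as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .rna_model import SecondaryStructure


@dataclass(frozen=True)
class AccuracyReport:
    tp: float
    fp: float
    fn: float
    sn: float
    ppv: float
    accuracy: float


def compare_structures(
    pred: SecondaryStructure, ref: SecondaryStructure
) -> tuple[int, int, int]:
    """(TP, FP, FN) base-pair counts under exact pair identity."""
    if pred.n != ref.n:
        raise ValueError(f"length mismatch: prediction n={pred.n}, reference n={ref.n}")
    tp = len(pred.pairs & ref.pairs)
    fp = len(pred.pairs - ref.pairs)
    fn = len(ref.pairs - pred.pairs)
    return tp, fp, fn


def _ratio(num: float, den: float, other_den: float) -> float:
    if den > 0:
        return num / den
    return 1.0 if other_den == 0 else 0.0


def accuracy(tp: float, fp: float, fn: float) -> AccuracyReport:
    """Sn, PPV and their mean from (possibly fractional, replicate-mean) counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    sn = _ratio(tp, tp + fn, tp + fp)
    ppv = _ratio(tp, tp + fp, tp + fn)
    return AccuracyReport(tp=tp, fp=fp, fn=fn, sn=sn, ppv=ppv, accuracy=(sn + ppv) / 2)


def score(pred: SecondaryStructure, ref: SecondaryStructure) -> AccuracyReport:
    return accuracy(*compare_structures(pred, ref))


def benchmark(
    items: Sequence[tuple[str, object, SecondaryStructure]],
    predict: Callable[[object, int], tuple[SecondaryStructure, int]],
    runs_per_item: int,
    master_seed: int,
) -> pd.DataFrame:
    """Replicate benchmark over (name, input, reference) items.

    ``predict(input, seed)`` returns a predicted structure and the number of
    generations used.  Every run gets a distinct child seed spawned from the
    master seed, so the whole table is reproducible.  Per-item failures are
    flagged in the ``failed`` column rather than aborting the batch.
    """
    seed_seq = np.random.SeedSequence(master_seed)
    rows = []
    for (name, item, ref), child in zip(
        items, seed_seq.spawn(len(items)), strict=True
    ):
        run_seeds = child.generate_state(runs_per_item) % (2**31)
        stats: list[tuple[int, int, int, float, float, float, int]] = []
        error: str | None = None
        for s in run_seeds:
            try:
                pred, generations = predict(item, int(s))
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                error = f"{type(exc).__name__}: {exc}"
                break
            tp, fp, fn = compare_structures(pred, ref)
            rep = accuracy(tp, fp, fn)
            stats.append((tp, fp, fn, rep.sn, rep.ppv, rep.accuracy, generations))
        if error is not None or not stats:
            rows.append({"name": name, "failed": error or "no runs"})
            continue
        arr = np.asarray(stats, dtype=float)
        means, sds = arr.mean(axis=0), arr.std(axis=0, ddof=0)
        rows.append(
            {
                "name": name,
                "TP": means[0],
                "FP": means[1],
                "FN": means[2],
                "Sn": means[3],
                "PPV": means[4],
                "Accuracy": means[5],
                "Accuracy_sd": sds[5],
                "Generations": means[6],
                "runs": len(stats),
                "failed": None,
            }
        )
    return pd.DataFrame(rows)


def mfe_overlap_analysis(
    mfe: SecondaryStructure,
    prediction_runs: Sequence[SecondaryStructure],
    ref: SecondaryStructure,
) -> pd.DataFrame:
    """Per-run PPV of the MFE pair set and of its overlap with predictions.

    For an MFE structure ``M`` and each predicted structure ``D``, reports the
    PPV (against the reference) of ``M``, of the shared pairs ``M ∩ D`` and of
    the remaining MFE pairs ``M \\ D``.  PPV over an empty subset is reported
    as 0 with the ``empty`` flag set.
    """

    def subset_ppv(pairs: frozenset) -> tuple[float, bool]:
        if not pairs:
            return 0.0, True
        return len(pairs & ref.pairs) / len(pairs), False

    ppv_m, _ = subset_ppv(mfe.pairs)
    rows = []
    for run_idx, d in enumerate(prediction_runs):
        common, common_empty = subset_ppv(mfe.pairs & d.pairs)
        remaining, remaining_empty = subset_ppv(mfe.pairs - d.pairs)
        rows.append(
            {
                "run": run_idx,
                "PPV_M": ppv_m,
                "PPV_common": common,
                "PPV_common_empty": common_empty,
                "PPV_remaining": remaining,
                "PPV_remaining_empty": remaining_empty,
            }
        )
    return pd.DataFrame(rows)
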
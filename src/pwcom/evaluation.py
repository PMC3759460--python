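"""Selection and correlation metrics for decoy ranking methods.

The field's standard summary of a quality-assessment score on one target:

* GDT1 — true GDT-TS of the top-1 ranked decoy (how good is the pick);
* avgGDT5 — mean true GDT-TS of the top-5 ranked decoys;
* Pearson — linear correlation between score and true GDT;
* Spearman — rank correlation between score and true GDT (average ranks on
  ties), the primary measure since only the ranking matters for selection.

Also provided: the average inter-score Spearman correlation matrix across
targets, and a leave-one-feature-out ablation of the pairwise combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .structure_io import ScoreTable

__all__ = ["QAMetrics", "evaluate", "cross_correlations", "ablation"]


@dataclass
class QAMetrics:
    gdt1: float
    avg_gdt5: float
    pearson: float
    spearman: float

    def as_dict(self) -> dict[str, float]:
        return {
            "GDT1": self.gdt1,
            "avgGDT5": self.avg_gdt5,
            "Pearson": self.pearson,
            "Spearman": self.spearman,
        }


def _safe_corr(fn, a: np.ndarray, b: np.ndarray) -> float:
    # a constant vector has no defined correlation; report 0 (no association)
    if np.ptp(a) < 1e-15 or np.ptp(b) < 1e-15:
        return 0.0
    return float(fn(a, b).statistic)


def rank_ids(score: ScoreTable, tiebreak: Optional[ScoreTable] = None) -> list[str]:
    """Decoy ids best-first by score; ties broken by the tiebreak table, then id."""
    tb = tiebreak.values if tiebreak is not None else {}
    return sorted(score.values, key=lambda d: (-score.values[d], -tb.get(d, 0.0), d))


def evaluate(
    score: ScoreTable,
    truth: dict[str, float],
    tiebreak: Optional[ScoreTable] = None,
) -> QAMetrics:
    """Selection metrics of one score column against true per-decoy GDT."""
    if set(score.values) != set(truth):
        raise ValueError(
            f"score table {score.name} and truth cover different decoys"
        )
    order = rank_ids(score, tiebreak)
    g = np.array([truth[d] for d in sorted(truth)])
    s = np.array([score.values[d] for d in sorted(truth)])
    top5 = order[: min(5, len(order))]
    return QAMetrics(
        gdt1=float(truth[order[0]]),
        avg_gdt5=float(np.mean([truth[d] for d in top5])),
        pearson=_safe_corr(pearsonr, s, g),
        spearman=_safe_corr(spearmanr, s, g),
    )


def cross_correlations(
    tables: Sequence[ScoreTable] | Sequence[Sequence[ScoreTable]],
    truth: Optional[dict[str, float] | Sequence[dict[str, float]]] = None,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between score columns.

    For one target pass a flat list of tables (plus optionally its truth map,
    included as a ``GDT`` column); for several targets pass a list of lists
    (and a list of truth maps) — the per-target matrices are averaged.
    """
    if tables and isinstance(tables[0], ScoreTable):
        tables = [list(tables)]
        truth = [truth] if truth is not None else None
    mats = []
    names = None
    for t_idx, cols in enumerate(tables):
        cols = list(cols)
        if truth is not None:
            tr = truth[t_idx]
            cols = [ScoreTable("GDT", dict(tr), "higher")] + cols
        ids = sorted(cols[0].values)
        for c in cols:
            if set(c.values) != set(ids):
                raise ValueError(f"score table {c.name} covers different decoys")
        if names is None:
            names = [c.name for c in cols]
        M = np.column_stack([[c.values[i] for i in ids] for c in cols])
        n = M.shape[1]
        R = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                R[a, b] = R[b, a] = _safe_corr(spearmanr, M[:, a], M[:, b])
        mats.append(R)
    avg = np.mean(mats, axis=0)
    np.fill_diagonal(avg, 1.0)
    return pd.DataFrame(avg, index=names, columns=names)


def ablation(
    targets: Sequence[tuple],
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-feature-out study of the pairwise combination.

    Runs leave-one-out training/evaluation on the full feature panel and on
    every panel with one column removed; returns one metrics row per
    configuration ("full" plus "no_<feature>" rows).
    """
    from .pairwise_model import loo_train_eval  # deferred: avoids import cycle

    full = loo_train_eval(targets, seed=seed)
    feature_names = targets[0][0].feature_names
    rows = [{"config": "full", **full["mean"]["PWCom"].as_dict()}]
    for name in feature_names:
        reduced = [(panel.drop(name), truth) for panel, truth in targets]
        res = loo_train_eval(reduced, seed=seed)
        rows.append({"config": f"no_{name}", **res["mean"]["PWCom"].as_dict()})
    return pd.DataFrame(rows).set_index("config")
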
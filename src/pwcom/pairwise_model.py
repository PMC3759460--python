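"""The pairwise two-stage combination score (PWCom).

For every unordered pair of decoys in a set, the difference of their feature
vectors (five scores: three single-model scores, PSPS, CGDT) is fed to two
small neural networks in sequence:

* model 1 decides whether the pair is *significantly* different in true
  quality (|ΔGDT| > 0.025 to the native);
* model 2, consulted only when model 1 says yes, decides which decoy of the
  pair is the better one.  Pairs with |ΔGDT| < 0.01 are removed from model
  2's training data to avoid teaching it near-ties.

Each network is a feed-forward classifier with one hidden layer of 3 sigmoid
units and a sigmoid output, trained full-batch with L-BFGS on weighted
cross-entropy.  A decoy's final score is its number of wins over the
pairwise tournament; ties in the resulting ranking are broken by CGDT, then
decoy id.

Logical symmetry of the pairwise formulation is enforced twice over: the
training set is augmented with mirrored pairs (−Δx with the mirrored label),
and at prediction time the outputs for Δx and −Δx are averaged, which makes
model 1 exactly even and model 2 exactly odd in Δx.

Training and testing follow a leave-one-out protocol at target level: each
decoy set is scored by models trained on the pairs of all other sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .evaluation import QAMetrics, evaluate
from .features import DEFAULT_FEATURE_ORDER, FeaturePanel
from .structure_io import ScoreTable

__all__ = [
    "SIG_CUTOFF",
    "TRAIN_FILTER",
    "PairRecord",
    "SigmoidNet",
    "PWComModels",
    "PWComResult",
    "make_pairs",
    "train_model1",
    "train_model2",
    "train_models",
    "compare_pair",
    "pwcom_score",
    "loo_train_eval",
]

SIG_CUTOFF = 0.025  # |ΔGDT| above which a pair counts as significantly different
TRAIN_FILTER = 0.01  # pairs with |ΔGDT| below this are dropped from model 2 training


@dataclass
class PairRecord:
    """One ordered decoy pair with its feature-difference vector and labels."""

    i: str
    j: str
    dfeat: np.ndarray
    dgdt: Optional[float] = None

    def __post_init__(self) -> None:
        self.dfeat = np.asarray(self.dfeat, dtype=float)

    @property
    def sig_label(self) -> Optional[bool]:
        if self.dgdt is None:
            return None
        return abs(self.dgdt) > SIG_CUTOFF

    @property
    def winner_label(self) -> Optional[int]:
        if self.dgdt is None:
            return None
        return 1 if self.dgdt > 0 else -1

    def mirrored(self) -> "PairRecord":
        return PairRecord(self.j, self.i, -self.dfeat,
                          None if self.dgdt is None else -self.dgdt)


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd


def make_pairs(panel: FeaturePanel, truth: Optional[dict[str, float]] = None) -> list[PairRecord]:
    """All N(N-1)/2 unordered pairs, once each, in lexicographic id order.

    Feature columns are z-scored within the decoy set before differencing so
    that scores on very different scales (energies vs. GDT fractions)
    contribute comparably.
    """
    ids = panel.ids
    if truth is not None:
        missing = set(ids) - set(truth)
        if missing:
            raise ValueError(f"truth missing decoys {sorted(missing)[:5]}")
    X = _zscore_columns(panel.matrix())
    row = {d: X[k] for k, d in enumerate(ids)}
    out = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            dgdt = None if truth is None else truth[i] - truth[j]
            out.append(PairRecord(i, j, row[i] - row[j], dgdt))
    return out


class SigmoidNet:
    """Feed-forward binary classifier: n_in → 3 sigmoid units → sigmoid output.

    Trained full-batch by L-BFGS on weighted cross-entropy with a small L2
    penalty; a few deterministic random restarts guard against bad local
    minima.  Fully deterministic given the seed.
    """

    def __init__(self, n_in: int, n_hidden: int = 3, l2: float = 1e-4,
                 max_iter: int = 300, n_restarts: int = 3, seed: int = 0):
        self.n_in = n_in
        self.n_hidden = n_hidden
        self.l2 = l2
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.seed = seed
        self.params_: Optional[np.ndarray] = None

    # parameter vector layout: W1 (h, n_in) | b1 (h) | w2 (h) | b2 (1)
    def _unpack(self, p: np.ndarray):
        h, n = self.n_hidden, self.n_in
        W1 = p[: h * n].reshape(h, n)
        b1 = p[h * n : h * n + h]
        w2 = p[h * n + h : h * n + 2 * h]
        b2 = p[-1]
        return W1, b1, w2, b2

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    def _loss_grad(self, p, X, y, w):
        W1, b1, w2, b2 = self._unpack(p)
        H = self._sigmoid(X @ W1.T + b1)  # (N, h)
        z = H @ w2 + b2
        pprob = self._sigmoid(z)
        eps = 1e-12
        loss = -(w * (y * np.log(pprob + eps) + (1 - y) * np.log(1 - pprob + eps))).sum()
        loss += self.l2 * (p @ p)
        dz = w * (pprob - y)  # (N,)
        gw2 = H.T @ dz
        gb2 = dz.sum()
        dH = np.outer(dz, w2) * H * (1 - H)  # (N, h)
        gW1 = dH.T @ X
        gb1 = dH.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]]) + 2 * self.l2 * p
        return loss, grad

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: Optional[np.ndarray] = None) -> "SigmoidNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        sample_weight = sample_weight / sample_weight.mean()
        rng = np.random.default_rng(self.seed)
        n_params = self.n_hidden * self.n_in + 2 * self.n_hidden + 1
        best = None
        for _ in range(self.n_restarts):
            p0 = rng.normal(scale=0.5, size=n_params)
            res = minimize(
                self._loss_grad, p0, args=(X, y, sample_weight),
                jac=True, method="L-BFGS-B",
                options={"maxiter": self.max_iter},
            )
            if best is None or res.fun < best.fun:
                best = res
        self.params_ = best.x
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("network is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        W1, b1, w2, b2 = self._unpack(self.params_)
        H = self._sigmoid(X @ W1.T + b1)
        return self._sigmoid(H @ w2 + b2)

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_hidden": self.n_hidden,
            "l2": self.l2,
            "max_iter": self.max_iter,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "params": None if self.params_ is None else self.params_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidNet":
        net = cls(d["n_in"], d["n_hidden"], d["l2"], d["max_iter"], d["n_restarts"], d["seed"])
        if d["params"] is not None:
            net.params_ = np.array(d["params"])
        return net


def _labeled_arrays(pairs: Sequence[PairRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([p.dfeat for p in pairs])
    dg = np.array([p.dgdt for p in pairs], dtype=float)
    if np.any(np.isnan(dg)):
        raise ValueError("all training pairs need a true GDT difference")
    return X, dg


def train_model1(pairs: Sequence[PairRecord], seed: int = 0,
                 sig_cutoff: float = SIG_CUTOFF) -> SigmoidNet:
    """Significance classifier: is |ΔGDT| > sig_cutoff for this pair?

    Mirror augmentation (−Δx, same label) teaches the evenness of the
    significance notion; inverse-frequency class weights counter the surplus
    of near-tied pairs in tight decoy sets.
    """
    X, dg = _labeled_arrays(pairs)
    y = (np.abs(dg) > sig_cutoff).astype(float)
    if y.min() == y.max():
        raise ValueError(
            "model 1 training needs both significant and non-significant pairs; "
            "decoy quality may be too uniform"
        )
    Xa = np.vstack([X, -X])
    ya = np.concatenate([y, y])
    freq = np.array([np.mean(ya == 0), np.mean(ya == 1)])
    w = 1.0 / (2.0 * freq[ya.astype(int)])
    net = SigmoidNet(X.shape[1], seed=seed)
    return net.fit(Xa, ya, w)


def train_model2(pairs: Sequence[PairRecord], seed: int = 0,
                 train_filter: float = TRAIN_FILTER) -> SigmoidNet:
    """Winner classifier: is decoy i better than decoy j (ΔGDT > 0)?

    Pairs with |ΔGDT| < train_filter are dropped; mirror augmentation
    (−Δx, flipped label) teaches the oddness of the comparison.
    """
    X, dg = _labeled_arrays(pairs)
    keep = np.abs(dg) >= train_filter
    X, dg = X[keep], dg[keep]
    y = (dg > 0).astype(float)
    if len(y) == 0 or y.min() == y.max():
        raise ValueError(
            "model 2 training needs winners in both orientations after filtering"
        )
    Xa = np.vstack([X, -X])
    ya = np.concatenate([y, 1 - y])
    net = SigmoidNet(X.shape[1], seed=seed + 1)
    return net.fit(Xa, ya)


@dataclass
class PWComModels:
    """The trained pair of classifiers plus the constants they were trained with."""

    model1: SigmoidNet
    model2: SigmoidNet
    sig_cutoff: float = SIG_CUTOFF
    train_filter: float = TRAIN_FILTER
    feature_order: tuple[str, ...] = DEFAULT_FEATURE_ORDER
    zscore_within_set: bool = True

    def significance_proba(self, dfeat: np.ndarray) -> np.ndarray:
        """Symmetrized model-1 probability: identical for Δx and −Δx."""
        X = np.atleast_2d(dfeat)
        return 0.5 * (self.model1.predict_proba(X) + self.model1.predict_proba(-X))

    def winner_proba(self, dfeat: np.ndarray) -> np.ndarray:
        """Antisymmetrized model-2 probability that i beats j: p(−Δx) = 1 − p(Δx)."""
        X = np.atleast_2d(dfeat)
        return 0.5 * (self.model2.predict_proba(X) + 1.0 - self.model2.predict_proba(-X))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model1": self.model1.to_dict(),
            "model2": self.model2.to_dict(),
            "sig_cutoff": self.sig_cutoff,
            "train_filter": self.train_filter,
            "feature_order": list(self.feature_order),
            "zscore_within_set": self.zscore_within_set,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PWComModels":
        d = json.loads(Path(path).read_text())
        return cls(
            SigmoidNet.from_dict(d["model1"]),
            SigmoidNet.from_dict(d["model2"]),
            d["sig_cutoff"],
            d["train_filter"],
            tuple(d["feature_order"]),
            d["zscore_within_set"],
        )


def train_models(pairs: Sequence[PairRecord], seed: int = 0,
                 feature_order: Sequence[str] = DEFAULT_FEATURE_ORDER) -> PWComModels:
    """Train both stages on a pooled labeled pair collection."""
    return PWComModels(
        train_model1(pairs, seed=seed),
        train_model2(pairs, seed=seed),
        feature_order=tuple(feature_order),
    )


def compare_pair(models: PWComModels, rec: PairRecord) -> str:
    """Two-stage decision for one pair: 'i_wins', 'j_wins' or 'no_decision'."""
    p_sig = float(models.significance_proba(rec.dfeat)[0])
    if p_sig <= 0.5:
        return "no_decision"
    p_win = float(models.winner_proba(rec.dfeat)[0])
    if p_win > 0.5:
        return "i_wins"
    if p_win < 0.5:
        return "j_wins"
    return "no_decision"


@dataclass
class PWComResult:
    """Winning counts over the pairwise tournament, with per-pair audit trail."""

    scores: dict[str, int]
    n_significant_pairs: int
    decisions: list[tuple[str, str, str]] = field(default_factory=list)

    def score_table(self) -> ScoreTable:
        return ScoreTable("PWCom", {k: float(v) for k, v in self.scores.items()}, "higher")

    def ranking(self, tiebreak: Optional[ScoreTable] = None) -> list[str]:
        """Decoys best-first; ties broken by the tiebreak table (CGDT), then id."""
        tb = tiebreak.values if tiebreak is not None else {}
        return sorted(
            self.scores,
            key=lambda d: (-self.scores[d], -tb.get(d, 0.0), d),
        )


def pwcom_score(models: PWComModels, panel: FeaturePanel) -> PWComResult:
    """Run the pairwise tournament over a decoy set and count wins per decoy.

    Each unordered pair is evaluated once; non-significant pairs award no
    points to either decoy.
    """
    pairs = make_pairs(panel)
    scores = {d: 0 for d in panel.ids}
    decided = 0
    decisions = []
    if pairs:
        D = np.array([p.dfeat for p in pairs])
        p_sig = models.significance_proba(D)
        p_win = models.winner_proba(D)
        for rec, ps, pw in zip(pairs, p_sig, p_win):
            if ps <= 0.5 or pw == 0.5:
                decisions.append((rec.i, rec.j, "no_decision"))
                continue
            winner = rec.i if pw > 0.5 else rec.j
            scores[winner] += 1
            decided += 1
            decisions.append((rec.i, rec.j, "i_wins" if winner == rec.i else "j_wins"))
    return PWComResult(scores, decided, decisions)


def loo_train_eval(
    targets: Sequence[tuple[FeaturePanel, dict[str, float]]],
    seed: int = 0,
) -> dict:
    """Leave-one-out training/evaluation at target level.

    For each target, both models are trained on the pairs pooled from all
    other targets and applied to the held-out one.  Returns per-target and
    mean selection metrics for PWCom and, for reference, for every single
    feature column.
    """
    if len(targets) < 2:
        raise ValueError("leave-one-out needs at least 2 targets")
    for panel, truth in targets:
        if truth is None:
            raise ValueError(f"target {panel.set_id} has no true GDT")

    all_pairs = [make_pairs(panel, truth) for panel, truth in targets]
    feature_names = targets[0][0].feature_names

    per_target: list[dict] = []
    for t, (panel, truth) in enumerate(targets):
        pool: list[PairRecord] = []
        for u, pairs in enumerate(all_pairs):
            if u != t:
                pool.extend(pairs)
        models = train_models(pool, seed=seed, feature_order=feature_names)
        result = pwcom_score(models, panel)
        cgdt_col = panel.column("CGDT") if "CGDT" in feature_names else None
        entry = {
            "target": panel.set_id,
            "result": result,
            "PWCom": evaluate(result.score_table(), truth, tiebreak=cgdt_col),
        }
        for col in panel.columns:
            entry[col.name] = evaluate(col, truth)
        per_target.append(entry)

    summary: dict[str, QAMetrics] = {}
    for name in ["PWCom", *feature_names]:
        ms = [e[name] for e in per_target]
        summary[name] = QAMetrics(
            gdt1=float(np.mean([m.gdt1 for m in ms])),
            avg_gdt5=float(np.mean([m.avg_gdt5 for m in ms])),
            pearson=float(np.mean([m.pearson for m in ms])),
            spearman=float(np.mean([m.spearman for m in ms])),
        )
    return {"per_target": per_target, "mean": summary}
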
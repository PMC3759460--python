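"""Structural alphabet over Cα angle triplets and the PSPS consensus score.

Local backbone geometry at residue ``i`` (1-based, ``3 <= i <= L-1``) is
described by four consecutive Cα atoms ``(i-2, i-1, i, i+1)`` as an angle
triplet ``(theta1, tau, theta2)``: the bend angle at atom ``i-1``, the
dihedral of the four atoms, and the bend angle at atom ``i``.  Triplets are
clustered into K = 17 states by a Gaussian mixture; each decoy then becomes a
sequence of L-3 state codes.

Because the dihedral is circular, the mixture is fitted in the embedding
``(theta1, sin tau, cos tau, theta2)``, which removes the ±180° seam; state
assignment uses the same embedding.

Given the state sequences of a whole decoy set, the position-specific
frequency matrix (PSFM) holds the per-position frequency of every state, and
a decoy's PSPS score is the sum over positions of the frequency of its own
state — a consensus score in structure-code space, bounded by L-3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .structure_io import CAStructure, ScoreTable, StructureError

__all__ = [
    "AngleTriplet",
    "StateModel",
    "StateSequence",
    "PSFM",
    "angle_triplets",
    "fit_state_model",
    "assign_states",
    "build_psfm",
    "psps",
    "psps_scores",
    "default_state_model",
]

N_STATES = 17


@dataclass(frozen=True)
class AngleTriplet:
    """Bend/dihedral/bend angles (degrees) of four consecutive Cα atoms."""

    theta1: float
    tau: float
    theta2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta1 <= 180.0 and 0.0 < self.theta2 <= 180.0):
            raise ValueError(f"bend angles must lie in (0, 180], got {self}")
        if not (-180.0 < self.tau <= 180.0):
            raise ValueError(f"dihedral must lie in (-180, 180], got {self}")


@dataclass
class StateSequence:
    """Per-position structure-code states (1..K) of one decoy, length L-3."""

    decoy_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class PSFM:
    """Position-specific state frequency matrix: (K, L-3), columns sum to 1."""

    freq: np.ndarray
    n_decoys: int

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.min() < 0 or self.freq.max() > 1:
            raise ValueError("PSFM entries must lie in [0, 1]")
        colsums = self.freq.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PSFM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.freq.shape[1]


@dataclass
class StateModel:
    """Gaussian mixture over embedded angle triplets (theta1, sin tau, cos tau, theta2).

    ``means`` is (K, 4) and ``covariances`` (K, 4, 4) in the embedded space;
    angles are degrees, the sin/cos components dimensionless.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        K = len(self.weights)
        if self.means.shape != (K, 4) or self.covariances.shape != (K, 4, 4):
            raise ValueError("StateModel shape mismatch")
        if abs(self.weights.sum() - 1.0) > 1e-9 or self.weights.min() < 0:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        # positive-definiteness check via Cholesky
        for k, C in enumerate(self.covariances):
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                raise ValueError(f"covariance of state {k + 1} not positive-definite") from None

    @property
    def K(self) -> int:
        return len(self.weights)

    def mean_triplets(self) -> list[AngleTriplet]:
        """Component means mapped back to (theta1, tau, theta2) degrees."""
        out = []
        for m in self.means:
            tau = np.degrees(np.arctan2(m[1], m[2]))
            if tau <= -180.0:
                tau += 360.0
            out.append(AngleTriplet(float(np.clip(m[0], 1e-9, 180.0)),
                                    float(tau),
                                    float(np.clip(m[3], 1e-9, 180.0))))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": self.K,
            "embedding": "theta1_sin_tau_cos_tau_theta2",
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StateModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["weights"]),
            np.array(payload["means"]),
            np.array(payload["covariances"]),
        )


def angle_triplets(s: CAStructure) -> list[AngleTriplet]:
    """Angle triplets for residues 3..L-1 (1-based), one per scored position."""
    X = s.coords
    L = len(X)
    b = np.diff(X, axis=0)  # bond vectors, length L-1
    norms = np.linalg.norm(b, axis=1)
    if np.any(norms < 1e-8):
        pos = int(np.argmin(norms))
        raise StructureError(f"{s.id}: coincident consecutive CA atoms at bond {pos + 1}")

    out: list[AngleTriplet] = []
    for i in range(3, L):  # 0-based window (i-3, i-2, i-1, i); 1-based residue i in [3, L-1] is i-1 here
        b1, b2, b3 = b[i - 3], b[i - 2], b[i - 1]
        # bend at the two middle atoms: angle between incoming and outgoing bonds
        theta1 = _vertex_angle(b1, b2)
        theta2 = _vertex_angle(b2, b3)
        # dihedral of the four atoms
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
            raise StructureError(
                f"{s.id}: undefined dihedral at residue position {i}"  # 1-based position i
            )
        x = float(n1 @ n2)
        y = float((b1 @ n2) * np.linalg.norm(b2))
        tau = float(np.degrees(np.arctan2(y, x)))
        if tau <= -180.0:
            tau += 360.0
        out.append(AngleTriplet(float(theta1), tau, float(theta2)))
    return out


def _vertex_angle(b_in: np.ndarray, b_out: np.ndarray) -> float:
    """Bend angle (degrees) at the vertex joining bond b_in to bond b_out."""
    cosang = float(-(b_in @ b_out) / (np.linalg.norm(b_in) * np.linalg.norm(b_out)))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    # three collinear points give a straight angle of 180 degrees
    return min(max(ang, 1e-9), 180.0)


def embed_triplets(triplets: Sequence[AngleTriplet]) -> np.ndarray:
    """Map triplets to the 4-D fitting space (theta1, sin tau, cos tau, theta2)."""
    arr = np.array([[t.theta1, t.tau, t.theta2] for t in triplets], dtype=float)
    tau = np.radians(arr[:, 1])
    return np.column_stack([arr[:, 0], np.sin(tau), np.cos(tau), arr[:, 2]])


def fit_state_model(
    training: Iterable[CAStructure] | np.ndarray,
    K: int = N_STATES,
    seed: int = 0,
) -> StateModel:
    """Fit the structural alphabet: a K-component Gaussian mixture on triplets.

    ``training`` is either a collection of Cα traces (triplets are pooled from
    all of them) or an already-embedded (N, 4) array.  Deterministic given
    ``seed``.
    """
    if isinstance(training, np.ndarray):
        X = np.asarray(training, dtype=float)
    else:
        trips: list[AngleTriplet] = []
        for s in training:
            trips.extend(angle_triplets(s))
        X = embed_triplets(trips)
    if len(X) < 10 * K:
        raise ValueError(f"need at least {10 * K} triplets to fit {K} states, got {len(X)}")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        random_state=seed,
        n_init=3,
        max_iter=300,
        reg_covar=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    if not gm.converged_:
        warnings.warn("EM did not converge; returning best parameters found", RuntimeWarning)
    return StateModel(gm.weights_, gm.means_, gm.covariances_)


def _weighted_log_densities(model: StateModel, X: np.ndarray) -> np.ndarray:
    """log(w_k) + log N(x | mu_k, C_k) for every point and state: (N, K)."""
    N = len(X)
    out = np.empty((N, model.K))
    for k in range(model.K):
        C = model.covariances[k]
        L = np.linalg.cholesky(C)
        diff = X - model.means[k]
        z = np.linalg.solve(L, diff.T)
        maha = (z**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = (
            np.log(model.weights[k])
            - 0.5 * (maha + logdet + 4 * np.log(2 * np.pi))
        )
    return out


def assign_states(triplets: Sequence[AngleTriplet], model: StateModel) -> np.ndarray:
    """Hard state assignment: argmax of weighted Gaussian density, 1-based states.

    Ties resolve to the lowest state index (argmax convention).
    """
    X = embed_triplets(triplets)
    ld = _weighted_log_densities(model, X)
    return ld.argmax(axis=1) + 1


def state_sequence(s: CAStructure, model: StateModel) -> StateSequence:
    """Convenience: triplets -> states for one structure."""
    return StateSequence(s.id, assign_states(angle_triplets(s), model))


def build_psfm(seqs: Sequence[StateSequence], K: int = N_STATES) -> PSFM:
    """Count state occurrences per position over the decoy pool, normalized."""
    if not seqs:
        raise ValueError("build_psfm needs at least one state sequence")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("state sequences have differing lengths")
    counts = np.zeros((K, width))
    for s in seqs:
        if s.states.min() < 1 or s.states.max() > K:
            raise ValueError(f"{s.decoy_id}: states outside 1..{K}")
        counts[s.states - 1, np.arange(width)] += 1
    return PSFM(counts / len(seqs), len(seqs))


def psps(seq: StateSequence, psfm: PSFM) -> float:
    """Position Specific Probability Sum: sum of the decoy's own state frequencies."""
    if len(seq) != psfm.width:
        raise ValueError(
            f"{seq.decoy_id}: sequence length {len(seq)} does not match PSFM width {psfm.width}"
        )
    return float(psfm.freq[seq.states - 1, np.arange(psfm.width)].sum())


def psps_scores(structures: Sequence[CAStructure], model: StateModel) -> ScoreTable:
    """PSPS for every member of a decoy set (states and PSFM computed internally)."""
    seqs = [state_sequence(s, model) for s in structures]
    psfm = build_psfm(seqs, model.K)
    return ScoreTable("PSPS", {q.decoy_id: psps(q, psfm) for q in seqs}, "higher")


def default_state_model() -> StateModel:
    """The packaged 17-state alphabet, fitted on a synthetic helix/strand/coil library."""
    path = Path(__file__).parent / "data" / "default_state_model.json"
    return StateModel.from_json(path)
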
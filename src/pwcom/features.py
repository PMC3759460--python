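"""Per-decoy feature panels for the pairwise classifier.

A panel holds five higher-is-better score columns per decoy set, in a fixed
order: three single-model scores (externally supplied tables, e.g. from
knowledge-based potentials such as OPUS-Ca, RW or DDFire, or the built-in
stand-in potential), plus the two consensus scores PSPS and CGDT computed
internally.  Lower-is-better columns (energies) are negated on entry so the
classifier always sees consistent sign semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .gdt import consensus_gdt, gdt_matrix
from .structcode import StateModel, default_state_model, psps_scores
from .structure_io import CAStructure, DecoySet, ScoreTable

__all__ = [
    "DEFAULT_FEATURE_ORDER",
    "FeaturePanel",
    "standin_potential",
    "standin_table",
    "build_panel",
]

DEFAULT_FEATURE_ORDER = ("OPUS-Ca", "RW", "DDFire", "PSPS", "CGDT")

# three stand-in parameterizations so the three single-model slots differ
_STANDIN_VARIANTS = {
    "OPUS-Ca": dict(bin_width=0.5, r_max=15.0, min_sep=3),
    "RW": dict(bin_width=1.0, r_max=12.0, min_sep=3),
    "DDFire": dict(bin_width=0.5, r_max=15.0, min_sep=5),
}


@dataclass
class FeaturePanel:
    """Aligned per-decoy score columns of one decoy set (all higher-is-better)."""

    set_id: str
    columns: list[ScoreTable]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("panel needs at least one column")
        ids = set(self.columns[0].values)
        for col in self.columns:
            if col.orientation != "higher":
                raise ValueError(f"panel column {col.name} must be oriented higher-is-better")
            if set(col.values) != ids:
                raise ValueError(f"panel column {col.name} covers different decoys")

    @property
    def ids(self) -> list[str]:
        return sorted(self.columns[0].values)

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def matrix(self) -> np.ndarray:
        """(N, F) feature matrix, rows ordered by sorted decoy id."""
        ids = self.ids
        return np.column_stack([[c.values[i] for i in ids] for c in self.columns])

    def column(self, name: str) -> ScoreTable:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"panel has no column {name!r}")

    def drop(self, name: str) -> "FeaturePanel":
        """A copy of the panel without the named column."""
        kept = [c for c in self.columns if c.name != name]
        if len(kept) == len(self.columns):
            raise KeyError(f"panel has no column {name!r}")
        return FeaturePanel(self.set_id, kept)


def _reference_distance_distribution() -> dict:
    path = Path(__file__).parent / "data" / "ca_distance_reference.json"
    return json.loads(path.read_text())


def _bin_counts(s: CAStructure, bin_width: float, r_max: float, min_sep: int) -> np.ndarray:
    X = s.coords
    L = len(X)
    d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    iu = np.triu_indices(L, k=min_sep)
    dist = d[iu]
    dist = dist[dist < r_max]
    nbins = int(round(r_max / bin_width))
    counts, _ = np.histogram(dist, bins=nbins, range=(0.0, r_max))
    return counts


def compute_reference_distribution(
    library: Sequence[CAStructure],
    bin_width: float = 0.5,
    r_max: float = 15.0,
    min_sep: int = 3,
) -> np.ndarray:
    """Observed Cα pair-distance frequencies per bin over a reference library."""
    nbins = int(round(r_max / bin_width))
    counts = np.zeros(nbins)
    for s in library:
        counts += _bin_counts(s, bin_width, r_max, min_sep)
    total = counts.sum()
    if total == 0:
        raise ValueError("reference library produced no pair distances below r_max")
    return counts / total


def standin_potential(
    s: CAStructure,
    observed_freq: Optional[np.ndarray] = None,
    bin_width: float = 0.5,
    r_max: float = 15.0,
    min_sep: int = 3,
) -> float:
    """Cα distance-bin log-odds pseudo-energy (lower is better).

    For every residue pair with sequence separation >= min_sep and distance
    below r_max, the energy contribution is -log(observed_freq / reference)
    where observed frequencies come from a native-like reference library and
    the reference state is the uniform-sphere expectation (density ∝ r²).
    Additive over pairs; rigid-motion invariant; empty interaction set → 0.
    """
    if observed_freq is None:
        ref = _reference_distance_distribution()
        key = f"{bin_width:g}_{r_max:g}_{min_sep}"
        if key not in ref:
            raise KeyError(f"no bundled reference distribution for bins {key}")
        observed_freq = np.array(ref[key])
    nbins = int(round(r_max / bin_width))
    if len(observed_freq) != nbins:
        raise ValueError("observed_freq length does not match binning")
    edges = np.linspace(0.0, r_max, nbins + 1)
    # uniform-density-in-a-sphere expectation for each shell, normalized
    shell = edges[1:] ** 3 - edges[:-1] ** 3
    ref_freq = shell / shell.sum()
    counts = _bin_counts(s, bin_width, r_max, min_sep)
    if counts.sum() == 0:
        return 0.0
    eps = 1e-8
    logodds = np.log((observed_freq + eps) / (ref_freq + eps))
    return float(-(counts * logodds).sum())


def standin_table(structures: Sequence[CAStructure], name: str) -> ScoreTable:
    """Stand-in potential scores for a whole decoy set (lower-is-better table)."""
    params = _STANDIN_VARIANTS.get(name, _STANDIN_VARIANTS["OPUS-Ca"])
    values = {s.id: standin_potential(s, **params) for s in structures}
    return ScoreTable(name, values, "lower")


def build_panel(
    decoy_set: DecoySet,
    external: Sequence[ScoreTable] = (),
    model: Optional[StateModel] = None,
    feature_order: Sequence[str] = DEFAULT_FEATURE_ORDER,
    cgdt: Optional[ScoreTable] = None,
) -> FeaturePanel:
    """Assemble the feature panel of a decoy set.

    CGDT and PSPS are computed from the structures (CGDT may be passed in if
    the pairwise GDT matrix was already computed); the remaining slots are
    filled from ``external`` tables matched by name, else from the stand-in
    potential.  All columns are normalized to higher-is-better.
    """
    ids = set(decoy_set.ids)
    ext = {t.name: t for t in external}
    for t in ext.values():
        missing = ids - set(t.values)
        if missing:
            raise ValueError(
                f"external table {t.name} missing decoys {sorted(missing)[:5]}"
            )

    columns: list[ScoreTable] = []
    for name in feature_order:
        if name in ext:
            col = ext[name].oriented()
            col = ScoreTable(name, {i: col.values[i] for i in ids}, "higher")
        elif name == "CGDT":
            col = cgdt if cgdt is not None else consensus_gdt(gdt_matrix(decoy_set))
        elif name == "PSPS":
            col = psps_scores(decoy_set.decoys, model or default_state_model())
        else:
            col = standin_table(decoy_set.decoys, name).oriented()
        columns.append(col)
    return FeaturePanel(decoy_set.target_id, columns)
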
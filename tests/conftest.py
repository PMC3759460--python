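import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwcom.structure_io import CAStructure
from pwcom.synthetic import SynthConfig, synth_decoys, synth_native, synth_scores

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_helix(L: int = 12, phase: float = 0.0) -> CAStructure:
    """Ideal α-helix Cα trace: rise 1.5 Å, radius 2.3 Å, 100° twist per residue."""
    k = np.arange(L)
    ang = np.radians(100.0 * k + phase)
    coords = np.column_stack([1.5 * k, 2.3 * np.cos(ang), 2.3 * np.sin(ang)])
    return CAStructure("helix", coords, k + 1)


def random_walk_structure(L: int, seed: int, scale: float = 2.2) -> CAStructure:
    """Random-walk Cα trace (not self-avoiding) for geometry stress tests."""
    rng = np.random.default_rng(seed)
    coords = np.cumsum(rng.normal(scale=scale, size=(L, 3)), axis=0)
    return CAStructure(f"rw{seed}", coords, np.arange(1, L + 1))


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()


@pytest.fixture(scope="session")
def small_decoy_set():
    """A 10-decoy synthetic set (L=40) shared by structure-level tests."""
    cfg = SynthConfig(L=40, n_decoys=10, seed=11)
    native = synth_native(cfg.L, cfg.seed)
    return synth_decoys(native, cfg)


@pytest.fixture(scope="session")
def panel_targets():
    """Four small targets with feature panels, shared by pipeline-level tests.

    CGDT is computed from the structures; the single-model and PSPS slots are
    synthetic scores with Spearman 0.5 to the truth.
    """
    from pwcom.features import build_panel

    targets = []
    for s in range(4):
        cfg = SynthConfig(L=40, n_decoys=14, seed=100 + s)
        native = synth_native(cfg.L, cfg.seed)
        ds = synth_decoys(native, cfg)
        ext = [
            synth_scores(ds.true_gdt, 0.5, seed=500 + 10 * s + k, name=n)[0]
            for k, n in enumerate(["OPUS-Ca", "RW", "DDFire", "PSPS"])
        ]
        targets.append((build_panel(ds, ext), ds.true_gdt))
    return targets


@pytest.fixture(scope="session")
def trained_models(panel_targets):
    """Models trained on the pooled pairs of the shared targets."""
    from pwcom.pairwise_model import make_pairs, train_models

    pool = []
    for panel, truth in panel_targets:
        pool.extend(make_pairs(panel, truth))
    return train_models(pool, seed=7)
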
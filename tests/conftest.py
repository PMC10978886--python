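"""Shared fixtures: synthetic scenes and the (expensive) trained SR stacks."""

import numpy as np
import pytest

from spidesr.degradation import DegradationConfig, make_training_pairs
from spidesr.io import PatchSet
from spidesr.synthetic import SceneSpec, generate_scene


def make_scenes(n, field_size=64, n_cells=12, seed0=0):
    """n clean nucleus-channel scenes as ImageGrids."""
    out = []
    for i in range(n):
        channels, _ = generate_scene(
            SceneSpec(field_size=field_size, n_cells=n_cells, seed=seed0 + i))
        out.append(channels["nucleus"])
    return out


@pytest.fixture(scope="session")
def sr_stacks():
    """Desk-preset blind-SR stacks trained on 64-scene banks, one per seed.

    Each entry maps seed -> (fitted BlindSuperResolver, TrainingPairs); the
    model is trained on the 6:2:2 train split, leaving the val/test splits
    held out.  Shared session-wide because training dominates runtime.
    """
    from spidesr.blindsr import BlindSuperResolver

    stacks = {}
    for seed in (0, 1, 2):
        scenes = make_scenes(64, seed0=1000 * (seed + 1))
        rng = np.random.default_rng(seed)
        pairs = make_training_pairs(PatchSet(scenes),
                                    DegradationConfig(scale=4), rng)
        model = BlindSuperResolver(random_state=seed).fit(pairs.train)
        stacks[seed] = (model, pairs)
    return stacks


@pytest.fixture(scope="session")
def validation_pairs_16():
    """16 held-out (hr, lr, kernel) pairs from fresh scenes (seed block 9000)."""
    scenes = make_scenes(16, seed0=9000)
    rng = np.random.default_rng(77)
    pairs = make_training_pairs(PatchSet(scenes), DegradationConfig(scale=4),
                                rng)
    return pairs.triples
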
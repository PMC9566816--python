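import numpy as np
import pytest


class ScriptedRNG:
    """Deterministic RNG stand-in returning pre-scripted draws.

    Each method pops from its own queue; scalars or arrays are returned
    as queued. Used to hand-check single update steps.
    """

    def __init__(self, *, uniform=(), standard_normal=(), random=(), integers=(), choice=()):
        self._q = {
            "uniform": list(uniform),
            "standard_normal": list(standard_normal),
            "random": list(random),
            "integers": list(integers),
            "choice": list(choice),
        }

    def _pop(self, name, size=None):
        val = self._q[name].pop(0)
        val = np.asarray(val, dtype=float) if np.ndim(val) else val
        if size is not None and np.ndim(val) == 0:
            return np.full(size, val, dtype=float)
        return val

    def uniform(self, low=0.0, high=1.0, size=None):
        return self._pop("uniform", size)

    def standard_normal(self, size=None):
        return self._pop("standard_normal", size)

    def random(self, size=None):
        return self._pop("random", size)

    def integers(self, low, high, size=None):
        return np.asarray(self._q["integers"].pop(0))

    def choice(self, n, size=None, replace=True):
        return np.asarray(self._q["choice"].pop(0))


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture
def blobs_dataset():
    """Well-separated two-class dataset, already normalized-ish."""
    from sparrowkelm.data_io import SynthConfig, synth_generate

    return synth_generate(
        SynthConfig(
            n_samples=120,
            n_informative_features=4,
            n_noise_features=2,
            class_separation=6.0,
            positive_fraction=0.5,
            seed=42,
        )
    )
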
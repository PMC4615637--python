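"""Named sub-streams of a single master seed.

Every source of randomness in the package (noise signal realizations,
afferent baseline draws, push-pull sign draws, connectivity, intrinsic
network noise, feedback wiring, teacher noise) pulls from its own named
sub-stream of one master seed, so any one component can be varied or held
fixed independently of the others, and replicate k of a component is
reproducible in isolation.
"""
from __future__ import annotations

import numpy as np

# stream labels (stable across versions; changing them changes all draws)
TRAIN_NOISE = 0
TEST_NOISE = 1
INPUT_BASELINE = 2
PUSH_PULL = 3
CONNECTIVITY = 4
NETWORK_NOISE = 5
GOLGI_INPUT = 6
FEEDBACK_WIRING = 7
TEACHER_NOISE = 8


def substream(seed: int, stream: int, replicate: int = 0) -> np.random.Generator:
    """Return the generator for (master seed, stream label, replicate index)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream), int(replicate)))
    return np.random.default_rng(ss)


def replicate_seed(seed: int, replicate: int) -> int:
    """Derive an independent master seed for replicate `replicate` (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(9999, int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))
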
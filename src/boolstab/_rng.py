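"""Counter-based RNG stream derivation.

All randomness in the package flows from one master seed.  Independent
streams are derived with :class:`numpy.random.SeedSequence` spawn keys so
that results do not depend on the order in which sub-tasks are executed.
"""

from __future__ import annotations

import numpy as np

# stream namespaces (first spawn-key component)
NETWORK_SAMPLING = 0
START_STATES = 1
BIT_FLIPS = 2
BOOTSTRAP = 3
EMISSION = 4


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Return a generator for the stream identified by ``key``.

    Distinct keys yield statistically independent streams; the same
    ``(master_seed, key)`` always yields the same stream.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
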
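"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def child_seeds(rng_seed: int, n: int) -> list[int]:
    """Fan a top-level seed out into ``n`` independent child seeds.

    Uses numpy's SeedSequence spawning, so any sub-computation can be
    reproduced in isolation from its child seed.  Values stay below 2**31.
    """
    ss = np.random.SeedSequence(rng_seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]
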
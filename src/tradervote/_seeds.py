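"""Counter-mode sub-seed derivation.

Every source of randomness in a run (population init, operators, fold
splits, the synthetic generator, each ensemble member) draws its seed from
the single global seed through :func:`derive_seed`, so streams are
independent yet fully reproducible.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31 - 1


def derive_seed(base: int, *stream: int) -> int:
    """Derive a sub-seed (< 2**31) from ``base`` and a stream counter path."""
    ss = np.random.SeedSequence([int(base), *(int(s) for s in stream)])
    return int(ss.generate_state(1)[0] % _MOD)
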
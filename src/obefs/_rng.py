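"""Seed plumbing.

Every stochastic component derives its seed from a single global seed through
``child_seed(seed, *key)``: a :class:`numpy.random.SeedSequence` with the global
seed as entropy and the key tuple as ``spawn_key``.  The scheme is deterministic,
collision-free across roles, and documented here so a run manifest (global seed +
role keys) suffices to reproduce any run.

Role keys used in this package:

========================  =======================================
``("selector", k)``       k-th selector inside an OBEFS run (0=fmboa, 1=lfcsa, 2=afa)
``("fitness", k)``        wrapper-fitness CV folds of the k-th selector
``("fold", i)``           i-th leave-one-person-out fold
``("synth",)``            synthetic table generation inside a pipeline config
``("classifier",)``       final classifier weight init / tie-breaking
========================  =======================================
"""

from __future__ import annotations

import numpy as np

_ROLE_CODES = {
    "selector": 1,
    "fitness": 2,
    "fold": 3,
    "synth": 4,
    "classifier": 5,
}


def child_seed(seed: int, role: str, index: int = 0) -> int:
    """Derive a 31-bit child seed for a named role from the global seed."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_ROLE_CODES[role], int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(seed: int, role: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, role, index))
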
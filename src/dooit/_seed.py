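"""Deterministic seed derivation.

All randomness in the pipeline flows from a single master seed.  Per-run,
per-level and per-trial seeds are derived with a splitmix64-style integer
hash so that no two stages share a stream and no hidden global state is
involved.  Derived seeds are kept below 2**31 so they are valid everywhere
(numpy, scikit-learn ``random_state``).
"""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _splitmix64(state: int) -> int:
    state = (state + 0x9E3779B97F4A7C15) & _MASK
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def derive_seed(master: int, *keys: int) -> int:
    """Hash ``master`` together with integer ``keys`` into a seed < 2**31.

    The same (master, keys) always yields the same seed; distinct key
    tuples yield independent streams for practical purposes.
    """
    state = _splitmix64(master & _MASK)
    for k in keys:
        state = _splitmix64((state ^ (k & _MASK)) & _MASK)
    return state % (1 << 31)
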
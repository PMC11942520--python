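"""Shared numeric helpers.

Two display conventions are used across the pipeline and must never be mixed:

* cohort percentages are *truncated* to the displayed precision
  (309/326 -> 94.7, 37/70 -> 52.8), and
* odds-ratio point estimates and confidence bounds are rounded *half-up*
  to two decimals at serialization time.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "truncate_percentage",
    "format_percentage",
    "round_half_up",
    "rng_stream",
]


def truncate_percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage ``100 * count / total`` truncated (not rounded) to `decimals`.

    Computed in integer arithmetic so the truncation is exact.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    scale = 10**decimals
    return (100 * count * scale // total) / scale


def format_percentage(count: int, total: int, decimals: int = 1) -> str:
    return f"{truncate_percentage(count, total, decimals):.{decimals}f}%"


def round_half_up(x, decimals: int = 2):
    """Round half away from zero for non-negative values; vectorized.

    ``round()`` rounds half to even, which does not match the convention of
    the clinical-statistics tools this pipeline mirrors.
    """
    scale = 10.0**decimals
    out = np.floor(np.asarray(x, dtype=float) * scale + 0.5) / scale
    if np.ndim(x) == 0:
        return float(out)
    return out


def rng_stream(seed: int, *key) -> np.random.Generator:
    """Independent, reproducible generator for a (seed, key...) pair.

    String keys are hashed with crc32 so streams are stable across runs and
    adding a new stream never perturbs existing ones.
    """
    ints = [int(seed)]
    for part in key:
        if isinstance(part, str):
            ints.append(zlib.crc32(part.encode("utf-8")))
        else:
            ints.append(int(part))
    return np.random.default_rng(np.random.SeedSequence(ints))
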
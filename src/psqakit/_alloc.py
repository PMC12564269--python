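"""Deterministic largest-remainder integer allocation."""

from __future__ import annotations

import numpy as np


def largest_remainder(total: int, proportions, priority=None) -> list[int]:
    """Allocate ``total`` items to bins proportionally, rounding by largest
    remainder.

    ``priority`` optionally gives per-bin tie-break ranks (lower wins) used
    when remainders are equal; by default earlier bins win ties.
    """
    props = np.asarray(proportions, dtype=np.float64)
    if total < 0:
        raise ValueError("total must be >= 0")
    if props.ndim != 1 or len(props) == 0 or np.any(props < 0):
        raise ValueError("proportions must be a non-negative 1-D vector")
    s = props.sum()
    if s <= 0:
        raise ValueError("proportions must sum to > 0")
    quotas = props / s * total
    counts = np.floor(quotas + 1e-9).astype(int)
    # round so that exact rational ties are ties despite float noise and
    # the priority rule decides them
    remainder = np.round(quotas - counts, 9)
    short = total - counts.sum()
    if priority is None:
        priority = np.arange(len(props))
    order = sorted(
        range(len(props)), key=lambda k: (-remainder[k], priority[k])
    )
    for k in order[:short]:
        counts[k] += 1
    return counts.tolist()
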
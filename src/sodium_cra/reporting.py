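"""Report-layer arithmetic shared by tables and summaries.

Tiny, deliberately boring helpers — percentages of a baseline, shares of
a total, pooled sex means, incremental totals — factored out so report
tables and their consistency checks use the same arithmetic.
"""

from __future__ import annotations

import numpy as np


def percent_of(part, whole):
    """100 * part / whole (elementwise); the '% averted' transform."""
    whole = np.asarray(whole, dtype=float)
    if np.any(whole <= 0):
        raise ValueError("percentage denominator must be > 0")
    return 100.0 * np.asarray(part, dtype=float) / whole


def shares_pct(values):
    """Each value as a percentage of the group total; sums to 100."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("share denominator must be > 0")
    return 100.0 * v / total


def pooled_mean(*group_means):
    """Unweighted pooled mean across groups (e.g. the two sexes)."""
    return float(np.mean(np.asarray(group_means, dtype=float)))


def incremental(total_a, total_b):
    """Additional events of scenario b over scenario a (b - a)."""
    return np.asarray(total_b, dtype=float) - np.asarray(total_a, dtype=float)
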
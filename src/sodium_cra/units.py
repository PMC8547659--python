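"""Unit conversions for dietary sodium.

Sodium intakes circulate in three units: survey and reformulation work is
done in mg/d, relative risks for stomach cancer are expressed per g/d, and
the blood-pressure dose-response (mm Hg per 100 mmol/d) needs mmol/d.
The molar mass of sodium, 22.99 g/mol, makes mg-per-mmol numerically equal
to g-per-mol, so all conversions reduce to one constant.
"""

from __future__ import annotations

import numpy as np

#: Molar mass of sodium in g/mol (equivalently mg per mmol).
M_NA = 22.99


def mg_to_mmol(mg):
    """Convert sodium mass (mg/d) to molar amount (mmol/d)."""
    return np.asarray(mg, dtype=float) / M_NA


def mmol_to_mg(mmol):
    """Convert sodium amount (mmol/d) to mass (mg/d)."""
    return np.asarray(mmol, dtype=float) * M_NA


def g_to_mmol(g):
    """Convert sodium mass (g/d) to molar amount (mmol/d)."""
    return np.asarray(g, dtype=float) * 1000.0 / M_NA


def mmol_to_g(mmol):
    """Convert sodium amount (mmol/d) to mass (g/d)."""
    return np.asarray(mmol, dtype=float) * M_NA / 1000.0
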
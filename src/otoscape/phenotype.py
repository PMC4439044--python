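"""Migratory phenotype bins.

Juvenile Chinook salmon are classed by fork length (FL) at outmigration:
fry (FL <= 55 mm), parr (55 < FL <= 75 mm), smolt (FL > 75 mm). The same
bins are applied to trap-measured juveniles and to adult back-calculated
sizes, so they live in one place.
"""

from __future__ import annotations

import numpy as np

PHENOTYPES: tuple[str, str, str] = ("fry", "parr", "smolt")

#: upper bin edges, mm; fry <= FRY_MAX < parr <= PARR_MAX < smolt
FRY_MAX_MM: float = 55.0
PARR_MAX_MM: float = 75.0


def assign_phenotype(fl_mm):
    """Classify fork length(s) into fry / parr / smolt.

    Parameters
    ----------
    fl_mm : float or array-like
        Fork length in mm; must be strictly positive.

    Returns
    -------
    str or ndarray of str
    """
    fl = np.asarray(fl_mm, dtype=float)
    if np.any(~np.isfinite(fl)) or np.any(fl <= 0):
        raise ValueError("fork length must be positive and finite")
    out = np.where(fl <= FRY_MAX_MM, "fry",
                   np.where(fl <= PARR_MAX_MM, "parr", "smolt"))
    if np.isscalar(fl_mm) or np.ndim(fl_mm) == 0:
        return str(out[()])
    return out


def phenotype_counts(fl_mm) -> dict[str, int]:
    """Count fish per phenotype from a sequence of fork lengths."""
    fl = np.asarray(fl_mm, dtype=float)
    if fl.size == 0:
        return {p: 0 for p in PHENOTYPES}
    labels = assign_phenotype(fl)
    return {p: int(np.sum(labels == p)) for p in PHENOTYPES}
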
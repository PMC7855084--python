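"""Orientation categories and laminar/longitudinal/radial indices.

Canals are placed into one of three major orientation categories from their
longitudinal angle omega and radial angle theta (degrees):

=============  ==================  =================
category       omega               theta
=============  ==================  =================
longitudinal   67.5 < omega <= 90  any
radial         omega <= 67.5       67.5 < theta <= 90
laminar        omega <= 67.5       theta <= 22.5
=============  ==================  =================

Anything else (omega <= 67.5 with 22.5 < theta <= 67.5) is oblique and is
excluded from the three indices' numerators but kept in their denominator,
so the indices need not sum to 1.  Indices are count-weighted for
single-section (2D) data and length-weighted for skeleton (3D) data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "OMEGA_LONGITUDINAL_DEG",
    "THETA_RADIAL_DEG",
    "THETA_LAMINAR_DEG",
    "OrientationIndices",
    "categorise",
    "indices_count",
    "indices_length",
    "classification_accuracy",
]

CATEGORIES = ("longitudinal", "radial", "laminar", "oblique")

OMEGA_LONGITUDINAL_DEG = 67.5
THETA_RADIAL_DEG = 67.5
THETA_LAMINAR_DEG = 22.5


def categorise(omega: float, theta: Optional[float] = None) -> str:
    """Map an (omega, theta) pair to its orientation category.

    Boundary convention: thresholds are upper-inclusive, so omega = 67.5
    falls in the lower band and theta = 22.5 is laminar.  omega = 0 (a
    perfectly transverse canal) is admitted into the lower band.  ``theta``
    may be ``None`` only for longitudinal canals (omega > 67.5), whose
    transverse projection can vanish.
    """
    if not 0.0 <= omega <= 90.0:
        raise ValueError(f"omega must be in [0, 90], got {omega}")
    if omega > OMEGA_LONGITUDINAL_DEG:
        return "longitudinal"
    if theta is None:
        raise ValueError(
            "theta is undefined but omega <= 67.5; cannot categorise"
        )
    if not 0.0 <= theta <= 90.0:
        raise ValueError(f"theta must be in [0, 90], got {theta}")
    if theta > THETA_RADIAL_DEG:
        return "radial"
    if theta <= THETA_LAMINAR_DEG:
        return "laminar"
    return "oblique"


@dataclass
class OrientationIndices:
    """Proportions of the canal network in each major orientation category.

    The denominator includes oblique canals, so
    ``longitudinal + radial + laminar <= 1``.
    """

    longitudinal: float
    radial: float
    laminar: float
    oblique_fraction: float
    weighting: str  # "count" | "length"
    total: float    # number of canals, or total network length

    def as_dict(self) -> dict:
        return {
            "longitudinal_index": self.longitudinal,
            "radial_index": self.radial,
            "laminar_index": self.laminar,
            "oblique_fraction": self.oblique_fraction,
            "weighting": self.weighting,
            "n_or_total_length": self.total,
        }


def indices_count(categories: Sequence[str]) -> OrientationIndices:
    """Count-weighted orientation indices (the 2D convention)."""
    if len(categories) == 0:
        raise ValueError("no canals to index")
    cats = list(categories)
    n = len(cats)
    return OrientationIndices(
        longitudinal=cats.count("longitudinal") / n,
        radial=cats.count("radial") / n,
        laminar=cats.count("laminar") / n,
        oblique_fraction=cats.count("oblique") / n,
        weighting="count",
        total=float(n),
    )


def indices_length(branches) -> OrientationIndices:
    """Length-weighted orientation indices (the 3D skeleton convention).

    Each branch contributes its Euclidean length to its category; the
    denominator is the total network length including oblique branches.
    Branches must already carry a ``category``.
    """
    lengths = {}
    total = 0.0
    for b in branches:
        if b.category is None:
            raise ValueError("branch has no category; classify it first")
        length = b.euclidean_length
        lengths[b.category] = lengths.get(b.category, 0.0) + length
        total += length
    if total <= 0:
        raise ValueError("total network length is zero")
    return OrientationIndices(
        longitudinal=lengths.get("longitudinal", 0.0) / total,
        radial=lengths.get("radial", 0.0) / total,
        laminar=lengths.get("laminar", 0.0) / total,
        oblique_fraction=lengths.get("oblique", 0.0) / total,
        weighting="length",
        total=total,
    )


def classification_accuracy(
    estimated: Sequence[str],
    truth: Sequence[str],
) -> pd.DataFrame:
    """Per-category agreement of estimated categories with ground truth.

    For each ground-truth category: the number of canals, the number the
    estimator assigned to that same category, and the percentage correct.
    Rows cover the three major categories (oblique is reported too, for
    completeness, when present in the truth).
    """
    if len(estimated) != len(truth):
        raise ValueError("estimated and truth lists must have equal length")
    est = np.asarray(estimated, dtype=object)
    tru = np.asarray(truth, dtype=object)
    rows = []
    cats = [c for c in CATEGORIES if c != "oblique"]
    if "oblique" in tru:
        cats.append("oblique")
    for cat in cats:
        mask = tru == cat
        n = int(mask.sum())
        n_correct = int((est[mask] == cat).sum())
        rows.append({
            "category": cat,
            "n_true": n,
            "n_correct": n_correct,
            "pct_correct": 100.0 * n_correct / n if n else np.nan,
        })
    return pd.DataFrame(rows)
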
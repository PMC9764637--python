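"""Outcome-based feature curation and composite clinical features.

A large engineered-feature catalogue is screened one feature at a time
against the censored outcome: a feature is retained only when its univariate
Harrell C-index falls outside a central "uninformative" band around 0.5
(default bounds (0.4, 0.6): discriminative in either orientation survives,
noise is discarded). The published pipeline describes the same screen with a
band printed ambiguously; symmetric bounds about chance are used here and
are configurable.

The age–size composite down-weights tumour size in older patients: by
default ``size * (reference_age / age)`` (reference 60 y), so a 2 cm tumour
at 30 counts like a 4 cm tumour at 60. Any user-supplied callable can
replace the default formula.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd

from .metrics import concordance_index


def univariate_cindex_filter(
    features: pd.DataFrame,
    time,
    event,
    low: float = 0.4,
    high: float = 0.6,
) -> pd.DataFrame:
    """Univariate C-index screen over a feature matrix.

    Returns the catalogue as a DataFrame with columns ``feature``,
    ``cindex`` and ``retained`` (True iff cindex <= low or cindex >= high).
    Constant features tie every pair and score exactly 0.5.
    """
    if not low < high:
        raise ValueError(f"need low < high, got ({low}, {high})")
    time = np.asarray(time, dtype=float).ravel()
    ev = np.asarray(event, dtype=int).ravel()
    if len(features) != len(time):
        raise ValueError("features and outcomes must be aligned by patient")
    if len(features) < 2 or ev.sum() == 0:
        raise ValueError("fewer than 2 comparable patient pairs")
    rows = []
    for name in features.columns:
        ci = concordance_index(features[name].to_numpy(float), time, ev)
        rows.append(
            {"feature": name, "cindex": ci, "retained": bool(ci <= low or ci >= high)}
        )
    return pd.DataFrame(rows)


def retained_features(catalog: pd.DataFrame) -> list[str]:
    return catalog.loc[catalog["retained"], "feature"].tolist()


def build_age_size_composite(
    age,
    size,
    reference_age: float = 60.0,
    formula: Optional[Callable[[np.ndarray, np.ndarray, float], np.ndarray]] = None,
) -> np.ndarray:
    """Age-balanced tumour size; vectorised over patients.

    Monotone increasing in size and decreasing in age; equals the raw size
    at the reference age.
    """
    age = np.asarray(age, dtype=float)
    size = np.asarray(size, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if np.any(size < 0):
        raise ValueError("tumor size must be non-negative")
    if formula is not None:
        return np.asarray(formula(age, size, reference_age), dtype=float)
    return size * (reference_age / age)
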
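"""Time-normalised evolution markers ("+" measures).

Follow-up intervals between the first (T1) and second (T2) CT
acquisition vary from patient to patient, so raw T1→T2 changes are not
comparable across a cohort.  The "+" marker linearly extrapolates the
observed change to a fixed one-year horizon:

    m_plus = m_T1 + (m_T2 - m_T1) * year_length / delta_days

i.e. an estimate of the measurement one year after T1.  The marker keeps
the units of the underlying measure (mm for diameters, mL for volumes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Days per year used for time normalisation.
DEFAULT_YEAR_LENGTH = 365.0

#: Below this inter-scan interval (days) the extrapolation coefficient
#: exceeds ~12 and the "+" marker becomes unstable.
SHORT_INTERVAL_DAYS = 30.0


@dataclass
class PairedStudy:
    """Paired T1/T2 measurements of one marker for one patient."""

    patient_id: str
    m_T1: float
    m_T2: float
    delta_days: float
    m_plus: float = None

    def __post_init__(self):
        if self.delta_days <= 0:
            raise ValueError("delta_days must be > 0")
        if self.m_plus is None:
            self.m_plus = annualize_measure(self.m_T1, self.m_T2, self.delta_days)


def annualize_measure(m1, m2, delta_days, year_length: float = DEFAULT_YEAR_LENGTH):
    """Extrapolate a T1→T2 change linearly to one year after T1.

    Parameters
    ----------
    m1, m2 : float or array
        Marker values at T1 and T2 (same units).
    delta_days : float or array
        Days between the scans, > 0.
    year_length : float
        Days per year (365 by default; exposed because day-count
        conventions differ).

    Returns
    -------
    float or array
        ``m1 + (m2 - m1) * year_length / delta_days``.
    """
    delta_days = np.asarray(delta_days, dtype=float)
    if np.any(delta_days <= 0):
        raise ValueError("delta_days must be > 0")
    if np.any(delta_days < SHORT_INTERVAL_DAYS):
        warnings.warn(
            f"inter-scan interval < {SHORT_INTERVAL_DAYS:.0f} days: the "
            "one-year extrapolation is unstable for very short intervals"
        )
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    out = m1 + (m2 - m1) * (year_length / delta_days)
    return float(out) if out.ndim == 0 else out


def add_evolution_markers(
    df: pd.DataFrame,
    markers,
    t1_suffix: str = "_t1",
    t2_suffix: str = "_t2",
    delta_col: str = "delta_days",
    t1_date_col: str = "t1_date",
    t2_date_col: str = "t2_date",
    year_length: float = DEFAULT_YEAR_LENGTH,
) -> pd.DataFrame:
    """Append ``<marker>_plus`` columns to a cohort table.

    The inter-scan interval is taken from ``delta_col`` when present,
    otherwise computed from the two date columns (ISO dates).  Rows with
    a missing T2 value keep NaN in the "+" column.
    """
    out = df.copy()
    if delta_col in out.columns:
        delta = out[delta_col].astype(float)
    elif t1_date_col in out.columns and t2_date_col in out.columns:
        t1 = pd.to_datetime(out[t1_date_col])
        t2 = pd.to_datetime(out[t2_date_col])
        delta = (t2 - t1).dt.days.astype(float)
        out[delta_col] = delta
    else:
        raise ValueError(
            f"need either a {delta_col!r} column or both "
            f"{t1_date_col!r} and {t2_date_col!r}"
        )
    for marker in markers:
        c1, c2 = marker + t1_suffix, marker + t2_suffix
        if c1 not in out.columns or c2 not in out.columns:
            raise ValueError(f"missing paired columns {c1!r}/{c2!r}")
        has = out[c2].notna() & delta.notna()
        plus = np.full(len(out), np.nan)
        if has.any():
            plus[has.to_numpy()] = annualize_measure(
                out.loc[has, c1].to_numpy(),
                out.loc[has, c2].to_numpy(),
                delta[has].to_numpy(),
                year_length,
            )
        out[marker + "_plus"] = plus
    return out
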
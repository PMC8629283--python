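"""Punch-quality statistics and best-punch labeling.

The unified punch statistics:

* effective force  ``F_eff = F / t``  (peak pad force over rise time, N/s),
* punch quality    ``q_p = F_eff * v``  (effective force times impact speed),
* relative quality ``q_rp = q_p / max(q_p)``  within a boxer's series,

plus top-fraction best-punch labeling and the polynomial fit of relative
quality against the conformance score x (how closely a punch matches the
trained optimal-punch model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats


def effective_force(F: float, t: float) -> float:
    """Effective punch force F/t: the harder and the faster the rise, the
    more effective the punch.

    Parameters are the peak pad force (N) and the rise time (s, from the
    beginning of the force increase to its maximum).
    """
    if t <= 0:
        raise ValueError("rise time must be positive (degenerate detection)")
    if F <= 0:
        raise ValueError("peak force must be positive")
    return F / t


def punch_quality(F_eff: float, v: float) -> float:
    """Punch quality q_p: the product of effective force and impact speed."""
    if F_eff <= 0 or v <= 0:
        raise ValueError("effective force and speed must be positive")
    return F_eff * v


def relative_quality(q_p_series) -> np.ndarray:
    """Normalize a series of punch qualities by its maximum.

    The maximum element maps to exactly 1; the series must be non-empty and
    strictly positive.
    """
    q = np.asarray(q_p_series, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality series")
    if np.any(q <= 0):
        raise ValueError("punch qualities must be strictly positive")
    return q / q.max()


def add_metrics(events: pd.DataFrame, per_boxer: bool = True) -> pd.DataFrame:
    """Append F_eff, q_p and q_rp columns to a punch-event table.

    Requires ``F_N``, ``t_s`` and ``v_mps`` columns.  Relative quality is
    normalized within each boxer's series when a ``boxer`` column is present
    and ``per_boxer`` is set, else over the whole table.
    """
    for col in ("F_N", "t_s", "v_mps"):
        if col not in events:
            raise ValueError(f"events table lacks required column {col!r}")
    out = events.copy()
    out["F_eff"] = out["F_N"] / out["t_s"]
    out["q_p"] = out["F_eff"] * out["v_mps"]
    if per_boxer and "boxer" in out:
        out["q_rp"] = out.groupby("boxer")["q_p"].transform(lambda s: s / s.max())
    else:
        out["q_rp"] = out["q_p"] / out["q_p"].max()
    return out


def label_best(events: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Label the top fraction of punches by q_p as ``best``.

    Exactly ``max(1, floor(fraction * N))`` punches are labeled; ties are
    broken deterministically by (q_p descending, punch_id ascending).  The
    selection is applied to the table as given — pool the per-hand data
    across boxers before calling for study-style pooled labeling.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if "q_p" not in events:
        raise ValueError("events table has no q_p column; compute metrics first")
    out = events.copy()
    n = len(out)
    if n == 0:
        raise ValueError("empty events table")
    n_best = max(1, int(np.floor(fraction * n)))
    ids = out["punch_id"].to_numpy() if "punch_id" in out else np.arange(n)
    order = np.lexsort((ids, -out["q_p"].to_numpy()))
    labels = np.full(n, "not_best", dtype=object)
    labels[order[:n_best]] = "best"
    out["label"] = labels
    return out


@dataclass
class QualityFit:
    """Least-squares polynomial of relative quality against conformance."""

    coefficients: np.ndarray  # ascending degree
    r: float  # Pearson correlation between x and q_rp

    def predict(self, x) -> np.ndarray:
        return npoly.polyval(np.asarray(x, dtype=float), self.coefficients)


def fit_quality_vs_conformance(x, q_rp, max_degree: int = 2) -> QualityFit:
    """Fit q_rp = c0 + c1*x + ... against the conformance score x in [0,1].

    Returns the ascending-degree coefficients and the Pearson correlation r
    between x and q_rp.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(q_rp, dtype=float)
    if x.size != y.size or x.size < max_degree + 1:
        raise ValueError("need at least max_degree + 1 (x, q_rp) points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all conformance values equal")
    coeffs = npoly.polyfit(x, y, max_degree)
    r = float(stats.pearsonr(x, y).statistic)
    return QualityFit(coefficients=coeffs, r=r)
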
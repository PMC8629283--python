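"""Published elite best-punch reference parameters.

Lower-limit parameters of the best straight punches of ten highly qualified
boxers (champions with over five years of training), per hand: peak pad force
F (N), rise time t (s, force onset to force maximum) and fist speed at impact
v (m/s).  These rows calibrate the synthetic-data generator's parameter
envelopes and serve as fixed inputs for the punch-quality statistics.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["boxer", "F_N", "t_s", "v_mps"]

# boxer, F (N), t (s), v (m/s)
_LEFT_ROWS = [
    (1, 884.16, 0.169, 12.10),
    (2, 821.82, 0.141, 13.01),
    (3, 921.81, 0.171, 9.84),
    (4, 790.22, 0.210, 11.54),
    (5, 906.56, 0.154, 9.91),
    (6, 994.77, 0.177, 10.40),
    (7, 963.12, 0.192, 9.21),
    (8, 1096.96, 0.181, 9.11),
    (9, 1285.42, 0.201, 7.47),
    (10, 1395.89, 0.231, 6.98),
]

_RIGHT_ROWS = [
    (1, 924.61, 0.155, 13.23),
    (2, 921.97, 0.138, 14.32),
    (3, 928.43, 0.164, 10.02),
    (4, 827.99, 0.234, 10.86),
    (5, 936.11, 0.160, 9.08),
    (6, 1100.56, 0.157, 11.15),
    (7, 985.82, 0.186, 9.16),
    (8, 1121.23, 0.179, 10.85),
    (9, 1295.42, 0.984, 7.55),
    (10, 1402.26, 0.200, 6.03),
]


def elite_best_punches(hand: str | None = None) -> pd.DataFrame:
    """Return the elite best-punch reference table as a DataFrame.

    Parameters
    ----------
    hand
        ``"left"``, ``"right"``, or ``None`` for both hands stacked (with a
        ``hand`` column).
    """
    left = pd.DataFrame(_LEFT_ROWS, columns=_COLUMNS).assign(hand="left")
    right = pd.DataFrame(_RIGHT_ROWS, columns=_COLUMNS).assign(hand="right")
    if hand == "left":
        return left
    if hand == "right":
        return right
    if hand is None:
        return pd.concat([left, right], ignore_index=True)
    raise ValueError(f"hand must be 'left', 'right' or None, got {hand!r}")


# Pooled min/max envelopes across both hands; the generator keeps every
# simulated elite punch inside these.
FORCE_ENVELOPE_N = (790.22, 1402.26)
RISE_TIME_ENVELOPE_S = (0.138, 0.984)
VELOCITY_ENVELOPE_MPS = (6.03, 14.32)

# Pooled maximum punch quality (F/t)*v of the reference table; the default
# normalizer for quality-based biofeedback scores.
ELITE_QUALITY_MAX = max(
    (F / t) * v for _, F, t, v in _LEFT_ROWS + _RIGHT_ROWS
)
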
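"""Published benchmark cohort summary used in worked examples.

Mean target-coverage statistics and monitor units reported for a
13-patient stage III lung-cancer IMRT comparison of the three planning
methods (conventional optimization, split-target optimization, and
base-dose-plan compensation).  These printed means serve as *inputs* to
the worked-example arithmetic (homogeneity-index recomputation and the
MU-derived peripheral-dose / beam-on-time deltas); the sandbox does not
attempt to reproduce the absolute clinical dose values themselves.
"""

from __future__ import annotations

#: Cohort means per planning method (Gy for D_x%, dimensionless CI/HI,
#: MU per fraction).
REFERENCE_COHORT: dict[str, dict[str, float]] = {
    "BDPC": {"d2_gy": 62.46, "d98_gy": 58.54, "d50_gy": 61.21,
             "ci": 0.88, "hi": 0.06, "mu": 1023.0},
    "CO":   {"d2_gy": 66.35, "d98_gy": 57.34, "d50_gy": 63.13,
             "ci": 0.85, "hi": 0.14, "mu": 890.0},
    "STO":  {"d2_gy": 64.21, "d98_gy": 57.80, "d50_gy": 61.92,
             "ci": 0.82, "hi": 0.10, "mu": 937.0},
}
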
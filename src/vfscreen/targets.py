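"""Published result values used as calibration targets.

These are the printed per-sex, per-strategy outcomes of the original analysis
(10-year horizon, two-year screening interval) and the old-age-subgroup
incremental effectiveness of the averaged "do screening" comparator.  They are
*inputs* to :func:`vfscreen.analysis.replication_search`, which selects the
modelling-convention combination that best reproduces them; they are never fed
back into the model itself.
"""

from __future__ import annotations

from .cascade import Strategy

__all__ = ["TABLE_BASE_CASE", "SUBGROUP_DO_SCREENING_DELTA_E", "POPULATION_WEIGHTS"]

# (effectiveness %, expected cost EUR, incremental radiation dose uSv)
TABLE_BASE_CASE = {
    ("female", Strategy.NO_SCREENING): (54.6, 60.0, 0.0),
    ("female", Strategy.XRAY_AFTER_VFA): (25.2, 881.0, 747.0),
    ("female", Strategy.VFA_ONLY): (25.2, 1202.0, 141.0),
    ("female", Strategy.XRAY_ONLY): (19.6, 998.0, 3394.0),
    ("male", Strategy.NO_SCREENING): (22.5, 27.0, 0.0),
    ("male", Strategy.XRAY_AFTER_VFA): (10.1, 504.0, 556.0),
    ("male", Strategy.VFA_ONLY): (10.1, 927.0, 147.0),
    ("male", Strategy.XRAY_ONLY): (5.0, 542.0, 3545.0),
}

# do-screening incidence reduction vs no screening, old-age subgroup (pp)
SUBGROUP_DO_SCREENING_DELTA_E = {"female": -41.0, "male": -32.8}

# 2013 national registration population by sex
POPULATION_WEIGHTS = {"female": 8_649_974, "male": 7_590_057}
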
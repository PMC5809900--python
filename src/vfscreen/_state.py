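"""Cohort occupancy container shared by the screening cascade and the engine.

The published state diagram has five health states (no VF, prevalent VF,
post VF, new VF, VFA-impossible).  Internally the cohort is tracked on a finer
grid that additionally records therapy status and whether a patient has ever
been diagnosed (first diagnosis triggers a one-off treatment-cost payoff and,
in the combined strategy, determines who still needs a confirmatory
radiograph).  The coarse published states are exposed via
:meth:`CompartmentVector.by_health_state`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["COMPARTMENTS", "HEALTH_STATES", "HEALTH_STATE_OF", "CompartmentVector"]

# fine-grained compartments:
#   novf_naive    no VF, never (falsely) diagnosed
#   novf_diag     no VF, false-positive diagnosis on record
#   prev_undx     prevalent VF, undiagnosed, untreated
#   prev_rx       prevalent VF, on therapy this cycle
#   post_dx       prior VF diagnosed & treated, therapy over, no new VF yet
#   post_rx       post VF, re-treated this cycle
#   postnv_undx   >=1 incident (new) VF, never diagnosed
#   postnv_dx     >=1 incident VF, diagnosed before, untreated
#   postnv_rx     >=1 incident VF, on therapy this cycle
#   imp_novf / imp_prev / imp_postnv   VFA-impossible stratum, by disease state
#   exited        counted new-VF exit (absorbing; retains excluded mass)
COMPARTMENTS = (
    "novf_naive", "novf_diag",
    "prev_undx", "prev_rx",
    "post_dx", "post_rx",
    "postnv_undx", "postnv_dx", "postnv_rx",
    "imp_novf", "imp_prev", "imp_postnv",
    "exited",
)

HEALTH_STATES = ("NO_VF", "PREVALENT_VF", "POST_VF", "NEW_VF_EXITED", "VFA_IMPOSSIBLE")

HEALTH_STATE_OF = {
    "novf_naive": "NO_VF", "novf_diag": "NO_VF",
    "prev_undx": "PREVALENT_VF", "prev_rx": "PREVALENT_VF",
    "post_dx": "POST_VF", "post_rx": "POST_VF",
    "postnv_undx": "POST_VF", "postnv_dx": "POST_VF", "postnv_rx": "POST_VF",
    "imp_novf": "VFA_IMPOSSIBLE", "imp_prev": "VFA_IMPOSSIBLE",
    "imp_postnv": "VFA_IMPOSSIBLE",
    "exited": "NEW_VF_EXITED",
}

_ON_THERAPY = ("prev_rx", "post_rx", "postnv_rx")


@dataclass
class CompartmentVector:
    """Cohort occupancy over the fine compartment grid; mass is conserved."""

    occupancy: dict = field(default_factory=lambda: {c: 0.0 for c in COMPARTMENTS})

    def __post_init__(self) -> None:
        missing = set(COMPARTMENTS) - set(self.occupancy)
        extra = set(self.occupancy) - set(COMPARTMENTS)
        if missing or extra:
            raise ValueError(f"bad compartment keys: missing={missing}, extra={extra}")
        for k, v in self.occupancy.items():
            if v < -1e-15:
                raise ValueError(f"negative occupancy in {k}: {v}")

    @classmethod
    def initial(cls, vf_prevalence: float) -> "CompartmentVector":
        occ = {c: 0.0 for c in COMPARTMENTS}
        occ["prev_undx"] = vf_prevalence
        occ["novf_naive"] = 1.0 - vf_prevalence
        return cls(occ)

    def __getitem__(self, key: str) -> float:
        return self.occupancy[key]

    def __setitem__(self, key: str, value: float) -> None:
        if key not in COMPARTMENTS:
            raise KeyError(key)
        self.occupancy[key] = value

    def copy(self) -> "CompartmentVector":
        return CompartmentVector(dict(self.occupancy))

    def total(self) -> float:
        return sum(self.occupancy.values())

    def on_therapy_mass(self) -> float:
        return sum(self.occupancy[c] for c in _ON_THERAPY)

    def by_health_state(self) -> dict:
        out = {s: 0.0 for s in HEALTH_STATES}
        for c, v in self.occupancy.items():
            out[HEALTH_STATE_OF[c]] += v
        return out

    def check_conserved(self, tol: float = 1e-12) -> None:
        t = self.total()
        if abs(t - 1.0) > tol:
            raise AssertionError(f"mass not conserved: total={t!r}")
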
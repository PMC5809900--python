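"""Per-screen diagnostic logic of the four strategies.

A screening event classifies every attending patient, starts one year of
anti-osteoporotic therapy for those testing positive, and accrues the event's
cost and radiation dose.  :func:`screen_profile` reduces a strategy and a
parameter set to per-patient probabilities and expected payoffs conditional on
true fracture status; :func:`apply_screen` pushes a cohort occupancy vector
through one event.

Strategy semantics
------------------
* ``XRAY_ONLY`` — every attender gets a radiograph (gold standard,
  sensitivity = specificity = 1): all fracture carriers start therapy, no
  false positives.
* ``VFA_ONLY`` — densitometric vertebral fracture assessment; classification
  by its sensitivity/specificity.  A patient's scan is unreadable with
  probability ``p_vfa_unreadable`` per event; patients found unreadable at the
  first screen enter the absorbing VFA-impossible state and are never screened
  again (disease progression continues).
* ``XRAY_AFTER_VFA`` — VFA for everyone; VFA-positives get a confirmatory
  radiograph before therapy, which removes false positives.  Confirmation is
  performed only at a patient's first positive test: previously diagnosed
  patients restart therapy on a positive VFA without a new radiograph.  By
  default unreadable scans are treated exactly as in ``VFA_ONLY`` (a
  persistent patient trait that the cascade cannot resolve), which makes the
  two VFA-based strategies clinically identical; the alternative convention
  sends unreadables straight to radiography.
* ``NO_SCREENING`` — the comparator; nothing happens, no dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from ._state import CompartmentVector
from .conventions import Conventions, DEFAULT_CONVENTIONS
from .parameters import ParameterSet, ValidationError

__all__ = ["Strategy", "ScreenProfile", "screen_profile", "apply_screen",
           "SCREENING_STRATEGIES"]


class Strategy(str, Enum):
    """The four compared strategies; values are stable CLI tokens."""

    NO_SCREENING = "no-screening"
    XRAY_AFTER_VFA = "xray-after-vfa"
    VFA_ONLY = "vfa-only"
    XRAY_ONLY = "xray-only"

    @classmethod
    def from_token(cls, token: str) -> "Strategy":
        try:
            return cls(token)
        except ValueError:
            raise ValueError(
                f"unknown strategy {token!r}; valid: {[s.value for s in cls]}"
            ) from None


SCREENING_STRATEGIES = (Strategy.XRAY_AFTER_VFA, Strategy.VFA_ONLY, Strategy.XRAY_ONLY)


@dataclass(frozen=True)
class ScreenProfile:
    """Probabilities and expected payoffs of one screening event.

    ``*_given_vf`` applies to undiagnosed fracture carriers, ``*_given_novf``
    to fracture-free attenders, ``*_prior_dx`` to carriers with an earlier
    diagnosis on record (re-screened and re-treated, but not re-confirmed).
    Costs cover tests plus the bundled physician visit; ``cost_first_diagnosis``
    is the one-off all-in treatment cost charged when a patient first tests
    positive.  ``p_unreadable_exit`` is the probability of entering the
    absorbing VFA-impossible state (first event only).
    """

    p_treat_given_vf: float = 0.0
    p_treat_given_novf: float = 0.0
    p_unreadable_exit: float = 0.0
    expected_dose_given_vf: float = 0.0
    expected_dose_given_novf: float = 0.0
    expected_cost_given_vf: float = 0.0
    expected_cost_given_novf: float = 0.0
    p_treat_prior_dx: float = 0.0
    expected_dose_prior_dx: float = 0.0
    expected_cost_prior_dx: float = 0.0
    cost_first_diagnosis: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_treat_given_vf", "p_treat_given_novf", "p_unreadable_exit",
                     "p_treat_prior_dx"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.p_treat_given_vf + self.p_unreadable_exit > 1.0 + 1e-12:
            raise ValidationError("p_treat_given_vf + p_unreadable_exit exceeds 1")
        for name in ("expected_dose_given_vf", "expected_dose_given_novf",
                     "expected_cost_given_vf", "expected_cost_given_novf",
                     "expected_dose_prior_dx", "expected_cost_prior_dx",
                     "cost_first_diagnosis"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def screen_profile(strategy: Strategy, params: ParameterSet,
                   conventions: Conventions = DEFAULT_CONVENTIONS,
                   first_event: bool = True) -> ScreenProfile:
    """Reduce one strategy to its per-event :class:`ScreenProfile`.

    ``first_event=False`` yields the profile for repeat screens, where the
    absorbing unreadable exit no longer applies (those patients left at the
    first event).
    """
    strategy = Strategy(strategy)
    if strategy is Strategy.NO_SCREENING:
        return ScreenProfile()

    u = params.p_vfa_unreadable
    se, sp = params.vfa_sensitivity, params.vfa_specificity
    xse, xsp = params.xray_sensitivity, params.xray_specificity

    if strategy is Strategy.XRAY_ONLY:
        return ScreenProfile(
            p_treat_given_vf=xse,
            p_treat_given_novf=1.0 - xsp,
            expected_dose_given_vf=params.dose_xray,
            expected_dose_given_novf=params.dose_xray,
            expected_cost_given_vf=params.cost_xray,
            expected_cost_given_novf=params.cost_xray,
            p_treat_prior_dx=xse,
            expected_dose_prior_dx=params.dose_xray,
            expected_cost_prior_dx=params.cost_xray,
            cost_first_diagnosis=params.cost_vf_treatment,
        )

    if strategy is Strategy.VFA_ONLY:
        return ScreenProfile(
            p_treat_given_vf=(1.0 - u) * se,
            p_treat_given_novf=(1.0 - u) * (1.0 - sp),
            p_unreadable_exit=u if first_event else 0.0,
            expected_dose_given_vf=params.dose_vfa,
            expected_dose_given_novf=params.dose_vfa,
            expected_cost_given_vf=params.cost_vfa,
            expected_cost_given_novf=params.cost_vfa,
            p_treat_prior_dx=(1.0 - u) * se,
            expected_dose_prior_dx=params.dose_vfa,
            expected_cost_prior_dx=params.cost_vfa,
            cost_first_diagnosis=params.cost_vf_treatment,
        )

    # XRAY_AFTER_VFA
    if conventions.unreadable_confirmed_by_xray:
        # unreadables go straight to radiography; no absorbing exit
        frac_xray_vf = (1.0 - u) * se + u
        frac_xray_novf = (1.0 - u) * (1.0 - sp) + u
        p_treat_vf = frac_xray_vf * xse
        p_retreat = (1.0 - u) * se + u
        unreadable_exit = 0.0
    else:
        # persistent unreadability: never classified, as in VFA_ONLY
        frac_xray_vf = (1.0 - u) * se
        frac_xray_novf = (1.0 - u) * (1.0 - sp)
        p_treat_vf = frac_xray_vf * xse
        p_retreat = (1.0 - u) * se
        unreadable_exit = u if first_event else 0.0
    return ScreenProfile(
        p_treat_given_vf=p_treat_vf,
        p_treat_given_novf=frac_xray_novf * (1.0 - xsp),
        p_unreadable_exit=unreadable_exit,
        expected_dose_given_vf=params.dose_vfa + frac_xray_vf * params.dose_xray,
        expected_dose_given_novf=params.dose_vfa + frac_xray_novf * params.dose_xray,
        expected_cost_given_vf=params.cost_vfa + frac_xray_vf * params.cost_xray,
        expected_cost_given_novf=params.cost_vfa + frac_xray_novf * params.cost_xray,
        # repeat screens: VFA only, therapy restarts without re-confirmation
        p_treat_prior_dx=p_retreat,
        expected_dose_prior_dx=params.dose_vfa,
        expected_cost_prior_dx=params.cost_vfa,
        cost_first_diagnosis=params.cost_vf_treatment,
    )


def apply_screen(profile: ScreenProfile,
                 occupancy: CompartmentVector) -> tuple[CompartmentVector, float, float]:
    """Push a cohort through one screening event.

    Returns the post-screen occupancy, the per-capita cost accrued by the
    event (tests, visits and first-diagnosis payoffs, undiscounted) and the
    per-capita radiation dose.  Mass is conserved exactly.
    """
    for k, v in occupancy.occupancy.items():
        if v < 0:
            raise ValidationError(f"negative occupancy in {k}: {v}")
    v = occupancy.copy()
    cost = 0.0
    dose = 0.0

    # absorbing unreadable exit happens before any classification or payoff
    u = profile.p_unreadable_exit
    if u > 0.0:
        for src, dst in (("novf_naive", "imp_novf"), ("novf_diag", "imp_novf"),
                         ("prev_undx", "imp_prev"), ("post_dx", "imp_prev"),
                         ("postnv_undx", "imp_postnv"), ("postnv_dx", "imp_postnv")):
            moved = v[src] * u
            v[src] -= moved
            v[dst] += moved

    # undiagnosed fracture carriers
    naive_vf = v["prev_undx"] + v["postnv_undx"]
    cost += naive_vf * profile.expected_cost_given_vf
    dose += naive_vf * profile.expected_dose_given_vf
    det_prev = v["prev_undx"] * profile.p_treat_given_vf
    det_postnv = v["postnv_undx"] * profile.p_treat_given_vf
    v["prev_undx"] -= det_prev
    v["prev_rx"] += det_prev
    v["postnv_undx"] -= det_postnv
    v["postnv_rx"] += det_postnv
    cost += (det_prev + det_postnv) * profile.cost_first_diagnosis

    # previously diagnosed carriers: re-screened, re-treated, not re-charged
    cost += (v["post_dx"] + v["postnv_dx"]) * profile.expected_cost_prior_dx
    dose += (v["post_dx"] + v["postnv_dx"]) * profile.expected_dose_prior_dx
    re_post = v["post_dx"] * profile.p_treat_prior_dx
    re_postnv = v["postnv_dx"] * profile.p_treat_prior_dx
    v["post_dx"] -= re_post
    v["post_rx"] += re_post
    v["postnv_dx"] -= re_postnv
    v["postnv_rx"] += re_postnv

    # fracture-free attenders; first false positive charged like a diagnosis
    no_pool = v["novf_naive"] + v["novf_diag"]
    cost += no_pool * profile.expected_cost_given_novf
    dose += no_pool * profile.expected_dose_given_novf
    fp = v["novf_naive"] * profile.p_treat_given_novf
    v["novf_naive"] -= fp
    v["novf_diag"] += fp
    cost += fp * profile.cost_first_diagnosis

    return v, cost, dose
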
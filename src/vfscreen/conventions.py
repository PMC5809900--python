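"""Modelling conventions the source description leaves open.

The published model is under-specified in several places (number of screening
events over the horizon, how a one-year therapy interacts with a two-year
cycle, whether recurrent fractures are counted, what happens to untreated
incident fractures, whether unreadable VFA images are resolved by radiography,
and whether procedure costs are billed separately).  Each open point is a
binary switch here; the 2**6 = 64 combinations form the space searched by
:func:`vfscreen.analysis.replication_search`.

The package default is the combination that preserves the published structural
identities (identical effectiveness of the two VFA-based strategies) while
matching the published cost and incidence structure; see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from itertools import product
from typing import Iterator

__all__ = ["Conventions", "DEFAULT_CONVENTIONS", "convention_space"]


@dataclass(frozen=True)
class Conventions:
    """One fully specified set of model conventions.

    Attributes
    ----------
    six_screening_events
        Screen at the start of every cycle *and* at the end of the horizon
        (t = 0, 2, ..., 10 with two-year cycles: six events).  If False, only
        the five cycle-start events occur.
    count_events
        Effectiveness counts every incident fracture (recurrent fractures
        included, so the tally can exceed 100 per 100 persons).  If False,
        only first new fractures per person are counted.
    untreated_exit_all
        An untreated incident fracture always leaves the simulation.  If
        False only the clinically recognised (symptomatic) fraction exits;
        asymptomatic fractures remain at risk, undetected.
    rr_prorated
        Treatment effect applied to one year of a multi-year cycle by hazard
        composition.  If False the relative risk applies to the whole cycle
        in which therapy starts.
    unreadable_confirmed_by_xray
        In the combined strategy, unreadable VFA images trigger a confirmatory
        radiograph.  If False unreadability is a persistent patient trait and
        those patients are never classified in either VFA-based strategy
        (which makes the two strategies clinically identical).
    procedure_cost_added
        Add the vertebral-procedure cost, weighted by the symptomatic
        fraction, to each incident-fracture payoff.  If False the procedure
        is considered bundled in the per-patient treatment cost.
    """

    six_screening_events: bool = True
    count_events: bool = True
    untreated_exit_all: bool = False
    rr_prorated: bool = False
    unreadable_confirmed_by_xray: bool = False
    procedure_cost_added: bool = False

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "Conventions":
        return replace(self, **kw)

    @property
    def label(self) -> str:
        """Compact bitstring, field order as declared."""
        return "".join(str(int(getattr(self, f.name))) for f in fields(self))


DEFAULT_CONVENTIONS = Conventions()


def convention_space() -> Iterator[Conventions]:
    """All 64 convention combinations, in deterministic field order.

    Iteration order is the documented tie-break order for the replication
    search: earlier combinations win ties.
    """
    names = [f.name for f in fields(Conventions)]
    for bits in product((False, True), repeat=len(names)):
        yield Conventions(**dict(zip(names, bits)))
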
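"""Premise/subject databases and the danger-detection life cycle.

The premise database records each zone's purpose, its pose-permission list
(e.g., no lying in the kitchen), rules for sensorized appliances (e.g., the
kettle may stay off its base for at most 90 s), and zone-transition
probabilities.  The subject database holds the library of safe behavioral
patterns learned for that person and the DTW-cost thresholds separating the
four behavior categories — normal (N), suspicious (S), dangerous (D),
critical (C).

The mechanism runs in three modes: *setup* (the operator writes permission
lists and alerting rules), *learning* (behavior is recorded and pattern
statistics accumulated; detailed sensor data are kept when limits are
exceeded or the subject presses the button), and *supervision* (behavior is
categorized against the safe library; D/C raise alerts and every S/D/C
event records detail data for human review).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import BehavioralPattern, StateVector, dtw, pattern_statistics

__all__ = [
    "BehaviorCategory",
    "Mode",
    "Zone",
    "ApplianceRule",
    "PremiseDB",
    "SubjectDB",
    "Violation",
    "Action",
    "check_permissions",
    "categorize",
    "run_mode",
    "review_queue",
]


class BehaviorCategory(enum.IntEnum):
    """Severity-ordered behavior categories."""

    N = 0  # normal
    S = 1  # suspicious
    D = 2  # dangerous
    C = 3  # critical


class Mode(str, enum.Enum):
    SETUP = "setup"
    LEARNING = "learning"
    SUPERVISION = "supervision"


@dataclass(frozen=True)
class Zone:
    id: str
    purpose: str = ""
    forbidden_poses: tuple[str, ...] = ()


@dataclass(frozen=True)
class ApplianceRule:
    id: str
    max_duration_s: float

    def __post_init__(self):
        if self.max_duration_s <= 0:
            raise ValueError("appliance max duration must be positive")


@dataclass(frozen=True)
class PremiseDB:
    """Zones, appliance rules, and zone-transition probabilities.

    Transition probabilities are validated (each zone's outgoing
    probabilities sum to 1) and stored for record annotation.
    """

    zones: dict[str, Zone] = field(default_factory=dict)
    appliances: dict[str, ApplianceRule] = field(default_factory=dict)
    transitions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for z, probs in self.transitions.items():
            if z not in self.zones:
                raise KeyError(f"transition source zone {z!r} not defined")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition probabilities from {z!r} sum to {total}")

    def to_json(self) -> str:
        return json.dumps({
            "zones": [{"id": z.id, "purpose": z.purpose,
                       "forbidden_poses": list(z.forbidden_poses)}
                      for z in self.zones.values()],
            "appliances": [{"id": a.id, "max_duration_s": a.max_duration_s}
                           for a in self.appliances.values()],
            "transitions": self.transitions,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PremiseDB":
        doc = json.loads(text)
        zones = {z["id"]: Zone(z["id"], z.get("purpose", ""),
                               tuple(z.get("forbidden_poses", ())))
                 for z in doc.get("zones", ())}
        apps = {a["id"]: ApplianceRule(a["id"], a["max_duration_s"])
                for a in doc.get("appliances", ())}
        return cls(zones, apps, doc.get("transitions", {}))


@dataclass(frozen=True)
class SubjectDB:
    """Safe-pattern library and N/S/D/C category thresholds for one subject.

    Thresholds are DTW costs: a sequence whose minimum cost to the safe
    library is at most ``suspicious`` is normal; beyond that the S, D and C
    bands apply (thresholds must be strictly ordered).
    """

    subject_id: str
    safe_patterns: tuple = ()
    suspicious: float = 0.5
    dangerous: float = 2.0
    critical: float = 6.0
    pattern_stats: dict[str, BehavioralPattern] = field(default_factory=dict)

    def __post_init__(self):
        if not self.suspicious < self.dangerous < self.critical:
            raise ValueError("thresholds must satisfy suspicious < dangerous < critical")
        object.__setattr__(self, "safe_patterns",
                           tuple(np.asarray(p, dtype=float) for p in self.safe_patterns))

    def to_json(self) -> str:
        return json.dumps({
            "subject_id": self.subject_id,
            "safe_patterns": [np.asarray(p).tolist() for p in self.safe_patterns],
            "thresholds": {"suspicious": self.suspicious,
                           "dangerous": self.dangerous,
                           "critical": self.critical},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubjectDB":
        doc = json.loads(text)
        th = doc.get("thresholds", {})
        return cls(doc["subject_id"],
                   tuple(doc.get("safe_patterns", ())),
                   suspicious=th.get("suspicious", 0.5),
                   dangerous=th.get("dangerous", 2.0),
                   critical=th.get("critical", 6.0))


@dataclass(frozen=True)
class Violation:
    kind: str      # "pose" or "appliance"
    detail: str


@dataclass(frozen=True)
class Action:
    kind: str                      # "record_detail" | "alert" | "db_update" | "pattern_logged"
    time: float
    event_id: str
    severity: BehaviorCategory | None = None
    payload: dict = field(default_factory=dict)


def check_permissions(state: StateVector, zone_id: str, appliance_events,
                      premise: PremiseDB) -> tuple[list[Violation], list[str]]:
    """Permission check for one time point.

    Violations: the dominant pose (argmax w_p; "undetermined" never
    violates) is on the zone's forbidden list, or an appliance event's
    elapsed time exceeds its rule.  ``appliance_events`` is an iterable of
    (appliance id, elapsed seconds).  Unknown appliances produce warnings,
    not violations.
    """
    if zone_id not in premise.zones:
        raise KeyError(f"unknown zone {zone_id!r}")
    violations: list[Violation] = []
    warnings: list[str] = []
    pose = state.dominant_pose
    if pose != "undetermined" and pose in premise.zones[zone_id].forbidden_poses:
        violations.append(Violation("pose", f"pose {pose!r} forbidden in zone {zone_id!r}"))
    for app_id, elapsed in appliance_events:
        rule = premise.appliances.get(app_id)
        if rule is None:
            warnings.append(f"unknown appliance {app_id!r}")
            continue
        if elapsed > rule.max_duration_s:
            violations.append(Violation(
                "appliance",
                f"appliance {app_id!r} active {elapsed:g} s > {rule.max_duration_s:g} s"))
    return violations, warnings


def categorize(sequence, subject: SubjectDB,
               n_violations: int = 0) -> tuple[BehaviorCategory, float]:
    """Behavior category of a sequence from its distance to safe behavior.

    The minimum DTW cost to any safe pattern selects the band (N up to the
    suspicious threshold, then S, D, C); each permission violation escalates
    the category by one band (saturating at C).
    """
    if not subject.safe_patterns:
        raise ValueError("safe-pattern library is empty: run the learning mode first")
    cost = min(dtw(sequence, p).cost for p in subject.safe_patterns)
    if cost <= subject.suspicious:
        cat = BehaviorCategory.N
    elif cost <= subject.dangerous:
        cat = BehaviorCategory.S
    elif cost <= subject.critical:
        cat = BehaviorCategory.D
    else:
        cat = BehaviorCategory.C
    cat = BehaviorCategory(min(int(cat) + max(0, int(n_violations)),
                               int(BehaviorCategory.C)))
    return cat, float(cost)


def _event_violations(ev: dict, premise: PremiseDB) -> int:
    n = 0
    state = ev.get("state")
    zone = ev.get("zone")
    if state is not None and zone is not None:
        v, _ = check_permissions(state, zone, ev.get("appliances", ()), premise)
        n = len(v)
    return n


def run_mode(mode: Mode | str, events, premise: PremiseDB,
             subject: SubjectDB) -> tuple[list[Action], SubjectDB]:
    """Process an event stream in one mode; returns actions and the
    (possibly updated) subject database.

    Events are dicts with a ``type`` ("sequence", "button", or "config" in
    setup), ``id``, ``t``, and for sequence events the state-vector
    ``sequence`` plus optional ``zone`` / ``state`` / ``appliances`` context
    for permission checking.  Setup writes permission lists and alert rules
    only; learning appends observed sequences to the safe library (never
    alerting); supervision categorizes against the library, alerts on D/C,
    and records detail data for every S/D/C event.
    """
    mode = Mode(mode)
    actions: list[Action] = []
    sub = subject

    if mode is Mode.SETUP:
        for ev in events:
            if ev.get("type") != "config":
                continue
            actions.append(Action("db_update", ev.get("t", 0.0), ev.get("id", ""),
                                  payload=ev.get("payload", {})))
        return actions, sub

    if mode is Mode.SUPERVISION and not sub.safe_patterns:
        raise ValueError("supervision requires a learned safe-pattern library")

    durations: list[tuple[str, float]] = []
    for ev in events:
        etype = ev.get("type")
        t = float(ev.get("t", 0.0))
        eid = str(ev.get("id", ""))
        if etype == "button":
            if mode is Mode.LEARNING:
                actions.append(Action("record_detail", t, eid,
                                      payload={"reason": "button"}))
            continue
        if etype != "sequence":
            continue
        seq = np.asarray(ev["sequence"], dtype=float)
        n_viol = _event_violations(ev, premise)
        if mode is Mode.LEARNING:
            sub = replace(sub, safe_patterns=sub.safe_patterns + (seq,))
            actions.append(Action("pattern_logged", t, eid))
            if "label" in ev and "duration" in ev:
                durations.append((ev["label"], float(ev["duration"])))
            if n_viol > 0:
                actions.append(Action("record_detail", t, eid,
                                      payload={"reason": "limit_exceeded",
                                               "violations": n_viol}))
        else:  # supervision
            cat, cost = categorize(seq, sub, n_violations=n_viol)
            if cat >= BehaviorCategory.S:
                actions.append(Action("record_detail", t, eid, severity=cat,
                                      payload={"cost": cost, "raw_data": eid}))
            if cat >= BehaviorCategory.D:
                actions.append(Action("alert", t, eid, severity=cat,
                                      payload={"cost": cost}))
    if mode is Mode.LEARNING and durations:
        sub = replace(sub, pattern_stats=pattern_statistics(durations))
    return actions, sub


def review_queue(actions) -> list[Action]:
    """Suspicious-event queue for human inspection.

    Detail-recording actions of severity S or worse, ordered by severity
    (most severe first) then time, deduplicated by event id.
    """
    seen: set[str] = set()
    picked = []
    for a in actions:
        if a.kind != "record_detail" or a.severity is None:
            continue
        if a.severity < BehaviorCategory.S:
            continue
        picked.append(a)
    picked.sort(key=lambda a: (-int(a.severity), a.time))
    out = []
    for a in picked:
        if a.event_id in seen:
            continue
        seen.add(a.event_id)
        out.append(a)
    return out
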
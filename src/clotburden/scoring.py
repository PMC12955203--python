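"""Segment-weighted clot burden scoring for the anterior circulation.

The clot burden score (CBS) grades thrombus extent on vessel imaging of one
anterior-circulation territory on a 0-10 scale: 10 means no visible thrombus,
0 means complete multisegment occlusion.  Points are deducted per involved
segment — 2 each for the supraclinoid internal carotid artery (ICA) and the
proximal and distal halves of the M1 trunk of the middle cerebral artery, and
1 each for the infraclinoid ICA, the anterior cerebral artery (ACA) and each
affected M2 branch.  The modified score (mCBS) up-weights ICA involvement:
thrombus anywhere in the ICA (infra- or supraclinoid) costs a single 3-point
deduction, reflecting the disproportionate effect of carotid occlusion on
collaterals and infarct growth; all other deductions are unchanged, so the
scale remains 0-10.

Both schemes count partially and completely occlusive thrombi alike; a
segment flag records presence, not degree.  Scoring is unilateral: one
territory per patient.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SEGMENTS",
    "SegmentStatus",
    "SchemeItem",
    "ScoringScheme",
    "ScoreResult",
    "CohortScoreReport",
    "UnsupportedSchemeError",
    "builtin_scheme",
    "compute_score",
    "score_cohort",
]

#: Scoreable vessel segments of one anterior-circulation territory, in
#: proximal-to-distal order.  These names double as the cohort CSV columns.
SEGMENTS: tuple[str, ...] = (
    "ica_infraclinoid",
    "ica_supraclinoid",
    "m1_proximal",
    "m1_distal",
    "aca",
    "m2_superior",
    "m2_inferior",
)


class UnsupportedSchemeError(ValueError):
    """Raised when a scheme name does not denote a built-in clot burden scheme."""


def _as_bool(name: str, value) -> bool:
    if isinstance(value, (bool,)) or type(value).__name__ == "bool_":
        return bool(value)
    if isinstance(value, numbers.Integral) and int(value) in (0, 1):
        return bool(int(value))
    if isinstance(value, numbers.Real) and float(value) in (0.0, 1.0):
        return bool(int(value))
    raise TypeError(f"segment flag {name!r} must be boolean (or 0/1), got {value!r}")


@dataclass(frozen=True)
class SegmentStatus:
    """Thrombus presence flags for the seven scoreable segments of one territory.

    Every flag is strictly boolean; a patient with an unknown segment is
    unscorable rather than scored on a guess.
    """

    ica_infraclinoid: bool
    ica_supraclinoid: bool
    m1_proximal: bool
    m1_distal: bool
    aca: bool
    m2_superior: bool
    m2_inferior: bool

    def __post_init__(self) -> None:
        for name in SEGMENTS:
            object.__setattr__(self, name, _as_bool(name, getattr(self, name)))

    @classmethod
    def from_mapping(cls, mapping) -> "SegmentStatus":
        """Build a status from any mapping with the seven segment keys."""
        missing = [s for s in SEGMENTS if s not in mapping or pd.isna(mapping[s])]
        if missing:
            raise ValueError(f"missing segment flag(s): {', '.join(missing)}")
        return cls(**{s: mapping[s] for s in SEGMENTS})

    def flags(self) -> dict[str, bool]:
        return {s: getattr(self, s) for s in SEGMENTS}

    def n_involved(self) -> int:
        return sum(self.flags().values())


@dataclass(frozen=True)
class SchemeItem:
    """One deduction item: fires when any of its segments carries thrombus."""

    label: str
    segments: frozenset
    deduction: int

    def triggered(self, status: SegmentStatus) -> bool:
        return any(getattr(status, s) for s in self.segments)


@dataclass(frozen=True)
class ScoringScheme:
    """A named deduction table over segment flags with a fixed maximum score.

    Custom integer-weighted variants are permitted (e.g. for weight-sweep
    experiments) provided every segment is covered by at least one item.
    """

    name: str
    items: tuple
    max_score: int = 10

    def __post_init__(self) -> None:
        covered = set()
        for item in self.items:
            if not (isinstance(item.deduction, int) and item.deduction > 0):
                raise ValueError(
                    f"item {item.label!r}: deduction must be a positive integer"
                )
            unknown = set(item.segments) - set(SEGMENTS)
            if unknown:
                raise ValueError(f"item {item.label!r}: unknown segments {unknown}")
            covered |= set(item.segments)
        uncovered = set(SEGMENTS) - covered
        if uncovered:
            raise ValueError(f"segments not covered by any item: {sorted(uncovered)}")

    @property
    def total_deduction(self) -> int:
        return sum(item.deduction for item in self.items)


@dataclass(frozen=True)
class ScoreResult:
    """Score of one patient under one scheme, with the items that fired."""

    patient_id: str
    scheme_name: str
    score: int
    triggered_items: tuple = field(default_factory=tuple)


def _cbs_scheme() -> ScoringScheme:
    return ScoringScheme(
        name="cbs",
        items=(
            SchemeItem("infraclinoid ICA", frozenset({"ica_infraclinoid"}), 1),
            SchemeItem("supraclinoid ICA", frozenset({"ica_supraclinoid"}), 2),
            SchemeItem("proximal M1", frozenset({"m1_proximal"}), 2),
            SchemeItem("distal M1", frozenset({"m1_distal"}), 2),
            SchemeItem("ACA", frozenset({"aca"}), 1),
            SchemeItem("M2 superior", frozenset({"m2_superior"}), 1),
            SchemeItem("M2 inferior", frozenset({"m2_inferior"}), 1),
        ),
    )


def _mcbs_scheme() -> ScoringScheme:
    # The ICA item merges both carotid segments into one 3-point deduction so
    # the deductions still sum to 10 and the scale stays 0-10.
    return ScoringScheme(
        name="mcbs",
        items=(
            SchemeItem(
                "ICA (infra- or supraclinoid)",
                frozenset({"ica_infraclinoid", "ica_supraclinoid"}),
                3,
            ),
            SchemeItem("proximal M1", frozenset({"m1_proximal"}), 2),
            SchemeItem("distal M1", frozenset({"m1_distal"}), 2),
            SchemeItem("ACA", frozenset({"aca"}), 1),
            SchemeItem("M2 superior", frozenset({"m2_superior"}), 1),
            SchemeItem("M2 inferior", frozenset({"m2_inferior"}), 1),
        ),
    )


_BUILTIN = {"cbs": _cbs_scheme, "mcbs": _mcbs_scheme}


def builtin_scheme(name: str) -> ScoringScheme:
    """Return a built-in scheme, ``"cbs"`` or ``"mcbs"`` (case-insensitive)."""
    key = str(name).lower()
    if key not in _BUILTIN:
        raise UnsupportedSchemeError(
            f"unsupported scheme {name!r}; built-in schemes are 'cbs' and 'mcbs'"
        )
    return _BUILTIN[key]()


def compute_score(
    status: SegmentStatus, scheme: ScoringScheme, patient_id: str = ""
) -> ScoreResult:
    """Score one patient: max_score minus the deductions of all fired items."""
    triggered = tuple(
        (item.label, item.deduction) for item in scheme.items if item.triggered(status)
    )
    score = scheme.max_score - sum(d for _, d in triggered)
    return ScoreResult(
        patient_id=str(patient_id),
        scheme_name=scheme.name,
        score=score,
        triggered_items=triggered,
    )


@dataclass
class CohortScoreReport:
    """Scores for the scorable rows plus per-row reasons for the rest."""

    results: list
    unscorable: list  # (patient_id, reason) pairs, in input order

    def scores(self) -> list:
        return [r.score for r in self.results]


def score_cohort(cohort: pd.DataFrame, scheme: ScoringScheme) -> CohortScoreReport:
    """Score every row of a cohort table; rows with missing flags are reported.

    The input needs the seven segment columns (0/1 or boolean) and a
    ``patient_id`` column; row order is preserved.  Rows missing any segment
    flag are collected into ``unscorable`` instead of being dropped silently.
    """
    results: list = []
    unscorable: list = []
    for _, row in cohort.iterrows():
        pid = str(row.get("patient_id", row.name))
        try:
            status = SegmentStatus.from_mapping(row)
        except (ValueError, TypeError) as exc:
            unscorable.append((pid, str(exc)))
            continue
        results.append(compute_score(status, scheme, patient_id=pid))
    return CohortScoreReport(results=results, unscorable=unscorable)
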
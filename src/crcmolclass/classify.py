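"""Rule-based molecular grouping of colorectal tumours.

Seven groups defined from MSI, CIN and the mutation calls, applied in
strict precedence (the order in which the groups were constructed):

1. MSI-positive and/or BRAF-mutant, irrespective of all other changes.
5. otherwise NRAS-mutant, irrespective of other changes.
3. otherwise KRAS- and/or PIK3CA-mutant, TP53 wild-type, CIN-positive.
4. otherwise KRAS- and/or PIK3CA-mutant, TP53 wild-type, CIN-negative.
2. otherwise CIN-positive and/or TP53-mutant, with wild-type KRAS and PIK3CA.
6. otherwise no alteration in any of the seven variables.
7. otherwise an 'atypical' mutation combination.

FBXW7 and the LOH calls take no part in any rule.  A tumour whose earliest
applicable rule cannot be decided because a needed call is missing is
``unclassifiable`` (the blocking marker is reported); group 7 therefore
remains "atypical combination", never "unknown".
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from .cohort import CORE_MARKERS, Cohort

__all__ = ["GroupAssignment", "assign_group", "classify_cohort", "GroupSummary"]

_MISSING = object()


@dataclasses.dataclass
class GroupAssignment:
    tumour_id: str | None
    group: str                      # "1".."7" or "unclassifiable"
    rule: str                       # human-readable rule that fired
    blocking_markers: list[str]     # markers whose absence blocked a decision


@dataclasses.dataclass
class GroupSummary:
    counts: dict[str, int]
    n: int

    @property
    def coverage_groups_1_to_5(self) -> float:
        """Fraction of all tumours falling in groups 1-5."""
        return sum(self.counts.get(g, 0) for g in "12345") / self.n


def _tri(profile: dict, marker: str):
    """Ternary lookup: 1, 0 or _MISSING."""
    v = profile.get(marker, None)
    if v is None or v is pd.NA or (isinstance(v, float) and pd.isna(v)):
        return _MISSING
    if v not in (0, 1):
        raise ValueError(f"unknown call {v!r} for marker {marker!r}")
    return v


# Three-valued (Kleene) condition evaluation: each term is (value, unknown)
# where value is True/False/None and unknown lists the markers that would be
# needed to settle a None.  A conjunction is False as soon as any conjunct is
# definitively False, even if another conjunct is unknown.

_TV = tuple  # (bool | None, list[str])


def _tv_any_altered(profile: dict, markers: tuple[str, ...]) -> _TV:
    unknown: list[str] = []
    for m in markers:
        v = _tri(profile, m)
        if v == 1:
            return True, []
        if v is _MISSING:
            unknown.append(m)
    return (None, unknown) if unknown else (False, [])


def _tv_not(term: _TV) -> _TV:
    val, unknown = term
    if val is None:
        return None, unknown
    return (not val), []


def _tv_and(*terms: _TV) -> _TV:
    unknown: list[str] = []
    for val, u in terms:
        if val is False:
            return False, []
        if val is None:
            unknown.extend(u)
    return (None, unknown) if unknown else (True, [])


def assign_group(profile: dict, tumour_id: str | None = None) -> GroupAssignment:
    """Assign one tumour to its molecular group.

    ``profile`` maps marker name → 1 (altered), 0 (wild-type) or NA/None
    (missing); only the seven core markers are consulted.  Pure function of
    the profile.  A missing call only blocks classification when the
    earliest applicable rule genuinely cannot be decided without it.
    """
    for m in profile:
        if m in ("tumour_id",):
            continue
        if m not in CORE_MARKERS and m not in ("fbxw7", "loh5q", "loh17p", "loh18q"):
            raise ValueError(f"unknown marker {m!r}")

    def undecidable(markers: list[str]) -> GroupAssignment:
        ms = sorted(set(markers))
        return GroupAssignment(
            tumour_id, "unclassifiable",
            f"undecidable: missing {', '.join(ms)}", ms)

    rules: list[tuple[_TV, str, str]] = []
    r1 = _tv_any_altered(profile, ("msi", "braf"))
    rules.append((r1, "1", "MSI+ and/or BRAF-mutant"))
    r2 = _tv_any_altered(profile, ("nras",))
    rules.append((r2, "5", "NRAS-mutant"))
    ras_pik = _tv_any_altered(profile, ("kras", "pik3ca"))
    tp53_wt = _tv_not(_tv_any_altered(profile, ("tp53",)))
    cin_alt = _tv_any_altered(profile, ("cin",))
    rules.append((_tv_and(ras_pik, tp53_wt, cin_alt), "3",
                  "KRAS/PIK3CA-mutant, TP53-WT, CIN+"))
    rules.append((_tv_and(ras_pik, tp53_wt, _tv_not(cin_alt)), "4",
                  "KRAS/PIK3CA-mutant, TP53-WT, CIN-"))
    cin_tp53 = _tv_any_altered(profile, ("cin", "tp53"))
    ras_pik_wt = _tv_not(ras_pik)
    rules.append((_tv_and(cin_tp53, ras_pik_wt), "2",
                  "CIN+ and/or TP53-mutant, KRAS/PIK3CA-WT"))
    all_wt = _tv_not(_tv_any_altered(profile, CORE_MARKERS))
    rules.append((all_wt, "6", "no detected alterations"))

    for (val, unknown), group, rule in rules:
        if val is True:
            return GroupAssignment(tumour_id, group, rule, [])
        if val is None:
            return undecidable(unknown)
    return GroupAssignment(tumour_id, "7", "atypical mutation combination", [])


def classify_cohort(cohort: Cohort) -> tuple[Cohort, GroupSummary]:
    """Classify every tumour; returns the cohort with its ``group`` column
    filled plus per-group counts and the groups-1-5 coverage fraction."""
    df = cohort.df.copy()
    groups = []
    for _, row in df.iterrows():
        profile = {m: row[m] for m in CORE_MARKERS}
        groups.append(assign_group(profile, row["tumour_id"]).group)
    df["group"] = pd.array(groups, dtype="string")
    counts = dict(Counter(groups))
    return Cohort(df), GroupSummary(counts=counts, n=len(df))
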
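"""Medication plans as sets of drug classes.

A medication plan is a nonempty subset of the five heart-failure drug
classes (ACE inhibitors, angiotensin receptor blockers, beta-blockers,
statins, calcium-channel blockers).  Its canonical string form is the
sorted "+"-joined class list, e.g. ``"ACEI+BB+Statin"``; there are at
most 31 distinct plans.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

DRUG_CLASSES: tuple[str, ...] = ("ACEI", "ARB", "BB", "CCB", "Statin")

_CLASS_SET = frozenset(DRUG_CLASSES)


class PlanError(ValueError):
    """Raised for empty plans or unknown drug classes."""


def canonical_plan(classes: Iterable[str] | str) -> str:
    """Return the canonical string form of a medication plan.

    Order- and duplicate-insensitive.  Accepts an iterable of drug-class
    names or an already-joined ``"+"`` string.
    """
    if isinstance(classes, str):
        classes = classes.split("+")
    unique = frozenset(classes)
    if not unique:
        raise PlanError("medication plan must contain at least one drug class")
    unknown = unique - _CLASS_SET
    if unknown:
        raise PlanError(f"unknown drug class(es): {sorted(unknown)}")
    return "+".join(sorted(unique))


def plan_classes(plan: str) -> frozenset[str]:
    """Return the set of drug classes of a canonical (or any) plan string."""
    return frozenset(canonical_plan(plan).split("+"))


def plan_jaccard(a: str, b: str) -> float:
    """Jaccard similarity of two plans' drug-class sets."""
    sa, sb = plan_classes(a), plan_classes(b)
    return len(sa & sb) / len(sa | sb)


def all_plans() -> list[str]:
    """All 31 nonempty drug-class subsets, canonical, lexicographic order."""
    plans = []
    for r in range(1, len(DRUG_CLASSES) + 1):
        for combo in combinations(DRUG_CLASSES, r):
            plans.append(canonical_plan(combo))
    return sorted(plans)
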
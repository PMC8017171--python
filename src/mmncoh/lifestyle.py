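"""CHAMPS-based active-lifestyle index.

The CHAMPS questionnaire lists 40 everyday activities.  Raters score each
activity's cognitive, physical and social demands on a 1 (no demands) to 5
(high demands) scale; an activity belongs to every domain whose mean rating
exceeds 3 (strictly).  A subject's lifestyle index is the mean over the three
domains of the fraction of that domain's activities the subject reports
performing within a 4-week span — a "variety of activities" measure in
[0, 1], not a frequency- or energy-weighted score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = ("cognitive", "physical", "social")
RATING_THRESHOLD = 3.0


@dataclass
class RatingTable:
    """Per-domain rater scores: ``ratings[domain]`` is an activities x raters frame."""

    ratings: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for domain, df in self.ratings.items():
            if domain not in DOMAINS:
                raise ValueError(f"unknown domain {domain!r}")
            vals = df.to_numpy(dtype=float)
            if vals.shape[1] < 1:
                raise ValueError("need at least one rater")
            if np.any((vals < 1) | (vals > 5)):
                raise ValueError("ratings must lie in [1, 5]")

    @property
    def activities(self) -> tuple[str, ...]:
        first = next(iter(self.ratings.values()))
        return tuple(first.index)

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        """Read a long CSV with columns (activity, domain, rater, rating)."""
        df = pd.read_csv(path)
        ratings = {
            domain: sub.pivot(index="activity", columns="rater", values="rating")
            for domain, sub in df.groupby("domain")
        }
        return cls(ratings=ratings)


@dataclass
class DomainAssignment:
    """Activity -> set-of-domains map derived from mean rater scores."""

    assigned: dict[str, set[str]]
    unassigned: tuple[str, ...]
    overrides: dict[str, set[str]] = field(default_factory=dict)

    def domain_activities(self, domain: str) -> tuple[str, ...]:
        return tuple(a for a, doms in self.assigned.items() if domain in doms)

    def counts(self) -> dict[str, int]:
        out = {d: len(self.domain_activities(d)) for d in DOMAINS}
        out["unassigned"] = len(self.unassigned)
        return out


def assign_domains(
    ratings: RatingTable,
    threshold: float = RATING_THRESHOLD,
    overrides: dict[str, set[str]] | None = None,
) -> DomainAssignment:
    """Assign each activity to every domain whose mean rating is > threshold.

    The inequality is strict: a mean of exactly 3.0 does not assign.  An
    activity may belong to several domains or to none.  ``overrides`` maps
    activity -> final domain set and models adjudicated reassignments (e.g.
    deferring to an independent senior panel when ratings disagree).
    """
    assigned: dict[str, set[str]] = {}
    for domain, df in ratings.ratings.items():
        means = df.mean(axis=1)
        for activity, m in means.items():
            assigned.setdefault(activity, set())
            if m > threshold:
                assigned[activity].add(domain)
    for activity, doms in (overrides or {}).items():
        assigned[activity] = set(doms)
    unassigned = tuple(a for a, doms in assigned.items() if not doms)
    return DomainAssignment(assigned=assigned, unassigned=unassigned,
                            overrides=dict(overrides or {}))


@dataclass(frozen=True)
class ActivityReport:
    """Activities one subject reports performing within a 4-week span."""

    subject: str
    activities: frozenset[str]


def activity_index(report: ActivityReport, assignment: DomainAssignment) -> float:
    """Lifestyle index: mean over domains of (performed / available) in [0, 1].

    Activities assigned to several domains count in each of them.
    """
    fractions = []
    for domain in DOMAINS:
        pool = assignment.domain_activities(domain)
        if not pool:
            raise ValueError(f"domain {domain!r} has no assigned activities")
        performed = sum(1 for a in pool if a in report.activities)
        fractions.append(performed / len(pool))
    return float(np.mean(fractions))


def n_reported(report: ActivityReport) -> int:
    """Raw count of reported activities (secondary descriptive output)."""
    return len(report.activities)


def score_reports(reports_df: pd.DataFrame, assignment: DomainAssignment) -> pd.DataFrame:
    """Score a CSV-style report table with columns (subject, activity).

    Returns one row per subject: lifestyle index and reported-activity count.
    """
    rows = []
    for subject, sub in reports_df.groupby("subject"):
        rep = ActivityReport(subject=str(subject), activities=frozenset(sub["activity"]))
        rows.append((subject, activity_index(rep, assignment), n_reported(rep)))
    return pd.DataFrame(rows, columns=["subject", "lifestyle_index", "n_reported"])


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha with rows = items (raters) and columns = observations.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums).
    Sample variances (ddof=1) throughout, so for k = 2 standardized items
    alpha equals the Spearman-Brown value 2 r / (1 + r) exactly.
    """
    x = np.asarray(matrix, dtype=float)
    k, n = x.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 observations")
    item_vars = x.var(axis=1, ddof=1)
    total_var = x.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
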
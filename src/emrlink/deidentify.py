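"""Free-text scrubbing and k-anonymity generalization of quasi-identifiers.

A record's quasi-identifiers (postal code, birth date, sex) are coarsened
by global recoding — one generalization level per field for the whole
table — walking the postal hierarchy first (6 chars → 5 → 4 → FSA →
suppressed), then the birth-date hierarchy (full date → year-month →
year → 5-year band → suppressed), until every equivalence class reaches
the group-size threshold ``k``. Records still in under-sized classes at
maximal generalization are suppressed (dropped) and counted.

An optional local-recoding mode generalizes only the records inside
under-sized classes, level by level, instead of the whole column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from emrlink.config import REDACTED, SUPPRESSED, AnonymizationPolicy


@dataclass
class EquivalenceClassReport:
    """Audit of equivalence-class sizes over the quasi-identifiers."""

    n_records: int
    class_sizes: dict[tuple, int]
    min_class_size: int
    postal_level: int = 0
    dob_level: int = 0
    n_suppressed: int = 0
    sizes_by_level: list[dict] = field(default_factory=list)

    @property
    def k_satisfied(self) -> bool:
        return self.n_records == 0 or self.min_class_size >= 1

    def satisfies(self, k: int) -> bool:
        return self.n_records == 0 or self.min_class_size >= k

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "min_class_size": self.min_class_size,
            "n_classes": len(self.class_sizes),
            "postal_level": self.postal_level,
            "dob_level": self.dob_level,
            "n_suppressed": self.n_suppressed,
            "class_size_distribution": sorted(self.class_sizes.values()),
            "sizes_by_level": self.sizes_by_level,
        }


def scrub_free_text(text: str, policy: AnonymizationPolicy | None = None) -> str:
    """Irrevocably replace identifier-shaped substrings with a redaction token.

    Patterns come from ``policy.scrub_patterns`` (titled person names and
    health-card-number shapes by default). Replacement text carries no
    information about the match, so the operation is not reversible.
    """
    policy = policy or AnonymizationPolicy()
    out = text
    for pattern in policy.scrub_patterns:
        out = re.sub(pattern, REDACTED, out)
    return out


def generalize_postal(code: str, level: int) -> str:
    """Postal-code hierarchy: full → 5 chars → 4 → 3 (FSA) → suppressed."""
    if not isinstance(code, str):
        code = "" if code is None or code != code else str(code)
    if level <= 0:
        return code
    if level >= 4:
        return SUPPRESSED
    return code[: 6 - level] if code else code


def generalize_dob(dob: str, level: int) -> str:
    """Birth-date hierarchy: full → year-month → year → 5-year band → suppressed.

    Dates are ISO strings; the 5-year band is on birth year
    (e.g. ``1960-1964``), which coarsens age to a 5-year range.
    """
    if level <= 0:
        return dob
    if level >= 4 or not dob:
        return SUPPRESSED
    if level == 1:
        return dob[:7]
    if level == 2:
        return dob[:4]
    year = int(dob[:4])
    lo = (year // 5) * 5
    return f"{lo}-{lo + 4}"


def _class_sizes(df: pd.DataFrame, quasi: tuple[str, ...]) -> pd.Series:
    if df.empty:
        return pd.Series(dtype=int)
    return df.groupby(list(quasi), dropna=False, observed=True)[quasi[0]].transform("size")


def _apply_levels(df: pd.DataFrame, postal_level: int, dob_level: int) -> pd.DataFrame:
    out = df.copy()
    if "postal_code" in out.columns:
        out["postal_code"] = out["postal_code"].astype(str).map(
            lambda c: generalize_postal(c, postal_level)
        )
    if "birth_date" in out.columns:
        out["birth_date"] = out["birth_date"].astype(str).map(
            lambda d: generalize_dob(d, dob_level)
        )
    return out


def _level_sequence(policy: AnonymizationPolicy) -> list[tuple[int, int]]:
    """The walk through the (postal, dob) generalization lattice.

    One field is exhausted before the other is touched; ``postal_first``
    selects which. The sequence is a chain, so the first satisfying state
    is also the least-coarse satisfying state along the walk.
    """
    n_p = len(policy.postal_hierarchy)
    n_d = len(policy.dob_hierarchy)
    seq = [(0, 0)]
    if policy.postal_first:
        seq += [(p, 0) for p in range(1, n_p)]
        seq += [(n_p - 1, d) for d in range(1, n_d)]
    else:
        seq += [(0, d) for d in range(1, n_d)]
        seq += [(p, n_d - 1) for p in range(1, n_p)]
    return seq


def generalize_until_k(
    records: pd.DataFrame, policy: AnonymizationPolicy | None = None
) -> tuple[pd.DataFrame, EquivalenceClassReport]:
    """Coarsen quasi-identifiers until every equivalence class has ≥ k members.

    Global recoding by default: the chosen (postal, dob) level pair applies
    to every record. Records whose class is still below k at maximal
    generalization are suppressed when ``policy.suppress`` is set.
    """
    policy = policy or AnonymizationPolicy()
    if records.empty:
        return records.copy(), EquivalenceClassReport(0, {}, 0)

    quasi = tuple(q for q in policy.quasi_identifiers if q in records.columns)
    if not quasi:
        raise ValueError("no quasi-identifier columns present")

    if policy.local_recoding:
        return _generalize_local(records, policy, quasi)

    sizes_by_level: list[dict] = []
    chosen = None
    for p_level, d_level in _level_sequence(policy):
        candidate = _apply_levels(records, p_level, d_level)
        sizes = _class_sizes(candidate, quasi)
        min_size = int(sizes.min())
        sizes_by_level.append(
            {"postal_level": p_level, "dob_level": d_level, "min_class_size": min_size}
        )
        if min_size >= policy.k:
            chosen = (p_level, d_level, candidate, sizes)
            break

    if chosen is None:
        # maximal generalization reached; suppress the residual small classes
        p_level, d_level = _level_sequence(policy)[-1]
        candidate = _apply_levels(records, p_level, d_level)
        sizes = _class_sizes(candidate, quasi)
        chosen = (p_level, d_level, candidate, sizes)

    p_level, d_level, out, sizes = chosen
    n_suppressed = 0
    if policy.suppress:
        keep = sizes >= policy.k
        n_suppressed = int((~keep).sum())
        out = out[keep.values]

    report = reidentification_audit(out, policy)
    report.postal_level = p_level
    report.dob_level = d_level
    report.n_suppressed = n_suppressed
    report.sizes_by_level = sizes_by_level
    return out.reset_index(drop=True), report


def _generalize_local(
    records: pd.DataFrame, policy: AnonymizationPolicy, quasi: tuple[str, ...]
) -> tuple[pd.DataFrame, EquivalenceClassReport]:
    """Per-record recoding: only under-sized classes are coarsened further."""
    out = records.copy()
    levels = pd.DataFrame(
        {"p": 0, "d": 0}, index=out.index
    )
    seq = _level_sequence(policy)
    for step, (p_level, d_level) in enumerate(seq[1:], start=1):
        current = out.copy()
        for i in out.index:
            current.loc[i, "postal_code"] = generalize_postal(
                str(records.loc[i, "postal_code"]), int(levels.loc[i, "p"])
            )
            current.loc[i, "birth_date"] = generalize_dob(
                str(records.loc[i, "birth_date"]), int(levels.loc[i, "d"])
            )
        sizes = _class_sizes(current, quasi)
        small = sizes < policy.k
        if not small.any():
            out = current
            break
        levels.loc[small.values, "p"] = p_level
        levels.loc[small.values, "d"] = d_level
        out = current
    else:
        for i in out.index:
            out.loc[i, "postal_code"] = generalize_postal(
                str(records.loc[i, "postal_code"]), int(levels.loc[i, "p"])
            )
            out.loc[i, "birth_date"] = generalize_dob(
                str(records.loc[i, "birth_date"]), int(levels.loc[i, "d"])
            )

    sizes = _class_sizes(out, quasi)
    n_suppressed = 0
    if policy.suppress:
        keep = sizes >= policy.k
        n_suppressed = int((~keep).sum())
        out = out[keep.values]
    report = reidentification_audit(out, policy)
    report.n_suppressed = n_suppressed
    return out.reset_index(drop=True), report


def reidentification_audit(
    records: pd.DataFrame, policy: AnonymizationPolicy | None = None
) -> EquivalenceClassReport:
    """Class-size distribution over the quasi-identifiers. Pure audit."""
    policy = policy or AnonymizationPolicy()
    quasi = tuple(q for q in policy.quasi_identifiers if q in records.columns)
    if records.empty or not quasi:
        return EquivalenceClassReport(0, {}, 0)
    grouped = records.groupby(list(quasi), dropna=False, observed=True).size()
    class_sizes = {k if isinstance(k, tuple) else (k,): int(v) for k, v in grouped.items()}
    return EquivalenceClassReport(
        n_records=len(records),
        class_sizes=class_sizes,
        min_class_size=int(grouped.min()),
    )
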
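"""NHS administrative hierarchy: practice -> PCN -> CCG -> STP.

English primary care is delivered by general practices, which group into
primary care networks (PCNs), clinical commissioning groups (CCGs) and
sustainability and transformation partnerships (STPs).  Prescribing
behaviour is analysed at all four levels, so practice-level item counts
must roll up the hierarchy.  The hierarchy is snapshot-static for a run.

Practices flagged non-"typical" (prisons, specialist community clinics)
are excluded from analysis; the flag is taken from the organisation
register rather than derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

#: ascending administrative levels
LEVELS = ("practice", "pcn", "ccg", "stp")
#: levels a practice rolls up to
PARENT_LEVELS = ("pcn", "ccg", "stp")


class HierarchyError(ValueError):
    """Inconsistent organisation register or practice-parent mapping."""


@dataclass(frozen=True)
class Organization:
    org_code: str
    name: str
    level: str
    is_typical: bool | None = None  # practice level only


@dataclass
class OrgHierarchy:
    """Validated register plus practice->parent maps for each upper level.

    The parent maps are partial: a practice missing from a map simply does
    not contribute to that level's roll-up (but stays in lower-level
    analyses).
    """

    register: pd.DataFrame  # org_code, name, level, is_typical
    parents: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level in PARENT_LEVELS:
            self.parents.setdefault(level, {})

    # -- lookups ---------------------------------------------------------
    def level_of(self, org_code: str) -> str:
        rows = self.register.loc[self.register["org_code"] == org_code]
        if rows.empty:
            raise HierarchyError(f"unknown organisation code {org_code!r}")
        return rows["level"].iloc[0]

    def parent_of(self, practice_code: str, level: str) -> str | None:
        if level not in PARENT_LEVELS:
            raise HierarchyError(f"not a parent level: {level!r}")
        return self.parents[level].get(practice_code)

    def typical_practices(self) -> set[str]:
        reg = self.register
        mask = (reg["level"] == "practice") & (reg["is_typical"] == True)  # noqa: E712
        return set(reg.loc[mask, "org_code"])

    def orgs_at(self, level: str) -> list[str]:
        return sorted(
            self.register.loc[self.register["level"] == level, "org_code"]
        )


def _as_frame(source, **read_kwargs) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, dtype=str, **read_kwargs)


_MAPPING_COLS = {"pcn": "pcn_code", "ccg": "ccg_code", "stp": "stp_code"}


def load_hierarchy(register, mapping) -> OrgHierarchy:
    """Build an :class:`OrgHierarchy` from register and mapping tables.

    ``register``: CSV path or DataFrame with ``org_code, name, level,
    is_typical`` (the typicality flag applies to practices only).
    ``mapping``: CSV path or DataFrame with ``practice_code, pcn_code,
    ccg_code, stp_code``; empty cells mean "unmapped at that level".

    Raises :class:`HierarchyError` on duplicate org codes within a level,
    a practice mapped to two different parents at one level, or a parent
    code absent from the register.  Orphan practices (no parent at some
    level) are retained and logged.
    """
    reg = _as_frame(register)
    needed = {"org_code", "name", "level"}
    if missing := needed - set(reg.columns):
        raise HierarchyError(f"register is missing columns: {sorted(missing)}")
    if "is_typical" not in reg.columns:
        reg["is_typical"] = pd.NA
    bad_levels = set(reg["level"]) - set(LEVELS)
    if bad_levels:
        raise HierarchyError(f"unknown levels in register: {sorted(bad_levels)}")
    dupes = reg[reg.duplicated(subset=["level", "org_code"], keep=False)]
    if not dupes.empty:
        raise HierarchyError(
            f"duplicate org codes within a level: {sorted(set(dupes['org_code']))[:5]}"
        )
    reg["is_typical"] = reg["is_typical"].map(
        lambda v: str(v).strip().lower() in {"true", "1", "yes", "y"}
        if pd.notna(v)
        else pd.NA
    )

    mp = _as_frame(mapping)
    if "practice_code" not in mp.columns:
        raise HierarchyError("mapping is missing column 'practice_code'")
    practice_codes = set(reg.loc[reg["level"] == "practice", "org_code"])
    unknown = set(mp["practice_code"]) - practice_codes
    if unknown:
        raise HierarchyError(
            f"mapping references practices absent from register: {sorted(unknown)[:5]}"
        )

    parents: dict[str, dict[str, str]] = {}
    for level, col in _MAPPING_COLS.items():
        if col not in mp.columns:
            parents[level] = {}
            continue
        sub = mp.loc[mp[col].notna() & (mp[col].astype(str).str.strip() != ""),
                     ["practice_code", col]]
        conflicts = (
            sub.drop_duplicates().groupby("practice_code")[col].nunique()
        )
        conflicted = conflicts[conflicts > 1]
        if not conflicted.empty:
            raise HierarchyError(
                f"practices mapped to multiple {level.upper()}s: "
                f"{sorted(conflicted.index)[:5]}"
            )
        level_codes = set(reg.loc[reg["level"] == level, "org_code"])
        missing_parents = set(sub[col]) - level_codes
        if missing_parents:
            raise HierarchyError(
                f"{level.upper()} codes in mapping absent from register: "
                f"{sorted(missing_parents)[:5]}"
            )
        parents[level] = dict(
            sub.drop_duplicates().itertuples(index=False, name=None)
        )
        orphans = practice_codes - set(parents[level])
        if orphans:
            log.warning(
                "%d practice(s) have no %s parent and are excluded from the "
                "%s roll-up (e.g. %s)",
                len(orphans), level.upper(), level.upper(),
                sorted(orphans)[0],
            )

    return OrgHierarchy(register=reg.reset_index(drop=True), parents=parents)


def members_of(hierarchy: OrgHierarchy, parent_code: str) -> list[str]:
    """All practices rolling up to ``parent_code``, in sorted order.

    Raises :class:`HierarchyError` for an unknown code or a practice-level
    code (practices have no members).
    """
    level = hierarchy.level_of(parent_code)
    if level == "practice":
        raise HierarchyError(
            f"{parent_code!r} is a practice; only PCN/CCG/STP have members"
        )
    return sorted(
        practice
        for practice, parent in hierarchy.parents[level].items()
        if parent == parent_code
    )


def filter_typical(records: pd.DataFrame, hierarchy: OrgHierarchy) -> pd.DataFrame:
    """Keep only records from practices flagged typical in the register.

    Records from practices absent from the register are dropped with a
    warning (robust to register/extract version skew); the number of
    dropped records is logged.
    """
    typical = hierarchy.typical_practices()
    known = set(
        hierarchy.register.loc[
            hierarchy.register["level"] == "practice", "org_code"
        ]
    )
    unknown_mask = ~records["practice_code"].isin(known)
    if unknown_mask.any():
        log.warning(
            "dropping %d record(s) from practice codes absent from the "
            "register", int(unknown_mask.sum()),
        )
    keep = records["practice_code"].isin(typical)
    dropped = int((~keep).sum())
    if dropped:
        log.info("typical-practice filter dropped %d of %d records",
                 dropped, len(records))
    return records.loc[keep].reset_index(drop=True)
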
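"""Oral-activity rule compliance and blood-brain-barrier penetration levels.

A physicochemical profile (MW, clogP, HBD, HBA, RB, PSA) is checked against a
named rule set; a compound with at most ``max_violations`` violations (one,
by default) is considered orally active.  logBBB values — base-10 log of the
brain/blood concentration ratio at steady state — are classified into four
penetration levels.  logBBB is always an input here, never computed.

Some published property tables print MW divided by 100 and PSA divided by 10;
readers take an explicit ``scaled`` flag rather than guessing (a silent
autodetect risks 100-fold unit errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PhysChemProfile",
    "Bound",
    "RuleSet",
    "ORAL_ACTIVITY_RULES",
    "RECOMMENDED_CNS_RULES",
    "BBB_LEVEL_LABELS",
    "rule_violations",
    "orally_active",
    "bbb_level",
    "classify_table",
    "read_physchem_csv",
]

PROPERTY_NAMES = ("MW", "logP", "HBD", "HBA", "RB", "PSA")


@dataclass(frozen=True)
class PhysChemProfile:
    """Physicochemical profile of one compound (raw units: g/mol, Å²)."""

    compound_id: str
    mw: float
    clogp: float
    hbd: int
    hba: int
    rb: int
    psa: float

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        if self.hbd < 0 or self.hba < 0 or self.rb < 0:
            raise ValueError("HBD/HBA/RB counts must be >= 0")
        if self.psa < 0:
            raise ValueError(f"psa must be >= 0, got {self.psa}")


@dataclass(frozen=True)
class Bound:
    """One-sided or two-sided bound with explicit strictness per side."""

    lo: float | None = None
    hi: float | None = None
    lo_strict: bool = False
    hi_strict: bool = False

    def violated(self, value: float) -> bool:
        if self.lo is not None and (value < self.lo or (self.lo_strict and value == self.lo)):
            return True
        if self.hi is not None and (value > self.hi or (self.hi_strict and value == self.hi)):
            return True
        return False


@dataclass(frozen=True)
class RuleSet:
    """Named set of per-property bounds plus the allowed violation count."""

    name: str
    bounds: dict = field(default_factory=dict)
    max_violations: int = 1

    def __post_init__(self) -> None:
        for prop, bound in self.bounds.items():
            if prop not in PROPERTY_NAMES:
                raise ValueError(f"unknown property {prop!r}")
            if bound.lo is not None and bound.hi is not None and not bound.lo < bound.hi:
                raise ValueError(f"{prop}: lower bound must be below upper bound")


#: Expanded oral-activity rules: 180 <= MW <= 500, -0.4 <= logP <= 5.6,
#: HBD < 5, HBA < 10, RB <= 10, PSA < 140 Å²; at most one violation allowed.
ORAL_ACTIVITY_RULES = RuleSet(
    name="oral_activity",
    bounds={
        "MW": Bound(lo=180, hi=500),
        "logP": Bound(lo=-0.4, hi=5.6),
        "HBD": Bound(hi=5, hi_strict=True),
        "HBA": Bound(hi=10, hi_strict=True),
        "RB": Bound(hi=10),
        "PSA": Bound(hi=140, hi_strict=True),
    },
    max_violations=1,
)

#: Tighter "recommended" upper bounds sometimes quoted alongside property
#: tables (MW 500, logP 5, HBD 3, HBA 7, RB 8, PSA 70 Å²).
RECOMMENDED_CNS_RULES = RuleSet(
    name="recommended",
    bounds={
        "MW": Bound(lo=180, hi=500),
        "logP": Bound(lo=-0.4, hi=5),
        "HBD": Bound(hi=3),
        "HBA": Bound(hi=7),
        "RB": Bound(hi=8),
        "PSA": Bound(hi=70),
    },
    max_violations=1,
)

RULE_SETS = {r.name: r for r in (ORAL_ACTIVITY_RULES, RECOMMENDED_CNS_RULES)}

BBB_LEVEL_LABELS = {
    0: "very high penetrant",
    1: "high penetrant",
    2: "medium penetrant",
    3: "low penetrant",
}


def rule_violations(profile: PhysChemProfile, rules: RuleSet = ORAL_ACTIVITY_RULES) -> list[str]:
    """Labels of the properties violating their bounds, in canonical order."""
    values = {
        "MW": profile.mw,
        "logP": profile.clogp,
        "HBD": profile.hbd,
        "HBA": profile.hba,
        "RB": profile.rb,
        "PSA": profile.psa,
    }
    return [
        prop
        for prop in PROPERTY_NAMES
        if prop in rules.bounds and rules.bounds[prop].violated(values[prop])
    ]


def orally_active(profile: PhysChemProfile, rules: RuleSet = ORAL_ACTIVITY_RULES) -> bool:
    """True when the number of violations does not exceed ``rules.max_violations``."""
    return len(rule_violations(profile, rules)) <= rules.max_violations


def bbb_level(logbbb: float) -> int:
    """Blood-brain-barrier penetration level of a logBBB value.

    Level 0 (very high): logBBB >= 0.7; level 1 (high): 0 <= logBBB < 0.7;
    level 2 (medium): -0.52 < logBBB < 0; level 3 (low): logBBB <= -0.52.
    The partition is total over the finite reals.
    """
    if not math.isfinite(logbbb):
        raise ValueError(f"logBBB must be finite, got {logbbb}")
    if logbbb >= 0.7:
        return 0
    if logbbb >= 0:
        return 1
    if logbbb > -0.52:
        return 2
    return 3


def read_physchem_csv(path, scaled: bool = False) -> pd.DataFrame:
    """Read a property CSV with header compound,MW,clogP,HBD,HBA,RB,PSA.

    ``scaled=True`` declares that the stored MW column is MW/100 and PSA is
    PSA/10 (a common compact printing); values are rescaled to raw units.
    """
    df = pd.read_csv(path)
    required = ["compound", "MW", "clogP", "HBD", "HBA", "RB", "PSA"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing column(s) {missing}")
    df = df.copy()
    if scaled:
        df["MW"] = df["MW"] * 100.0
        df["PSA"] = df["PSA"] * 10.0
    return df


def _profiles(df: pd.DataFrame) -> list[PhysChemProfile]:
    return [
        PhysChemProfile(
            compound_id=r.compound, mw=r.MW, clogp=r.clogP,
            hbd=int(r.HBD), hba=int(r.HBA), rb=int(r.RB), psa=r.PSA,
        )
        for r in df.itertuples()
    ]


def classify_table(
    profiles: pd.DataFrame,
    logbbb: pd.DataFrame | None = None,
    rules: RuleSet = ORAL_ACTIVITY_RULES,
) -> dict:
    """Per-compound rule report plus BBB levels and per-level counts.

    ``profiles`` must be in raw units (use :func:`read_physchem_csv` with the
    appropriate ``scaled`` flag).  ``logbbb``, when given, is a table with
    columns compound,logBBB; compounds missing from it are reported as
    unmatched rather than failing.
    """
    report = profiles[["compound"]].copy()
    viols = [rule_violations(p, rules) for p in _profiles(profiles)]
    report["violations"] = [";".join(v) for v in viols]
    report["n_violations"] = [len(v) for v in viols]
    report["orally_active"] = [len(v) <= rules.max_violations for v in viols]

    unmatched: list[str] = []
    level_counts: dict[int, int] = {}
    if logbbb is not None and len(logbbb):
        levels = logbbb.copy()
        levels["bbb_level"] = [bbb_level(v) for v in levels["logBBB"]]
        report = report.merge(levels[["compound", "bbb_level"]], on="compound", how="left")
        unmatched = sorted(
            set(report.loc[report["bbb_level"].isna(), "compound"])
            | (set(levels["compound"]) - set(report["compound"]))
        )
        counted = report["bbb_level"].dropna().astype(int)
        level_counts = counted.value_counts().sort_index().to_dict()
    return {
        "rules": rules.name,
        "report": report,
        "level_counts": level_counts,
        "n_orally_active": int(report["orally_active"].sum()),
        "unmatched": unmatched,
    }
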
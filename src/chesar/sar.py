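"""Selectivity and stereoselectivity tabulation from compound Ki tables.

The selectivity index SI = Ki(AChE)/Ki(BChE) measures the preference of an
inhibitor for butyrylcholinesterase over acetylcholinesterase (SI > 1 means
BChE-selective, since a lower Ki means tighter binding).  Stereoselectivity of
an enzyme toward a pseudo-enantiomeric pair (cinchonine-type vs
cinchonidine-type, which differ at the C8/C9 stereocenters but behave like
enantiomers) is the ratio of their Ki values for the same enzyme.

Printed values in activity tables mix precisions: ratios >= 10 are rounded to
the nearest integer, ratios < 10 to two significant figures.  Raw values are
always carried next to the printed ones; comparisons against printed numbers
should use :func:`printed_tolerance` (half a unit in the last printed digit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SarError",
    "PairingError",
    "RatioEntry",
    "round_ratio",
    "printed_tolerance",
    "selectivity_index",
    "stereoselectivity",
    "pair_pseudo_enantiomers",
    "ki_range",
    "selectivity_table",
    "stereoselectivity_table",
]

#: Pseudo-enantiomer partner series (numerator -> denominator in ratio tables).
PSEUDO_ENANTIOMER_PAIRS = {"CN": "CD", "DHCN": "DHCD"}

KI_COLUMNS = {"BChE": "Ki_BChE_uM", "AChE": "Ki_AChE_uM"}


class SarError(ValueError):
    """Base class for SAR-table errors."""


class PairingError(SarError):
    """Raised when pseudo-enantiomer pairing preconditions are violated."""


@dataclass(frozen=True)
class RatioEntry:
    """A Ki ratio with its raw value and table-rounded printed value."""

    label: str
    numerator_id: str
    denominator_id: str
    value: float
    printed_value: float


def round_ratio(value: float) -> float:
    """Round a ratio with the mixed table convention.

    Ratios >= 10 go to the nearest integer (half away from zero); ratios
    below 10 keep two significant figures.
    """
    if value >= 10:
        return float(math.floor(value + 0.5))
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, 1 - exponent)


def printed_tolerance(printed: str | float) -> float:
    """Half a unit in the last printed digit of ``printed``.

    Pass the printed string ("533", "0.056", "5.0") to preserve trailing
    zeros; a float falls back to its repr.
    """
    text = printed if isinstance(printed, str) else repr(float(printed))
    if "." in text:
        return 0.5 * 10.0 ** (-len(text.split(".")[1].rstrip()))
    return 0.5


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise SarError(f"{name} must be > 0, got {value}")


def selectivity_index(
    ki_ache: float, ki_bche: float, label: str = "SI",
    numerator_id: str = "AChE", denominator_id: str = "BChE",
) -> RatioEntry:
    """SI = Ki(AChE)/Ki(BChE); values above 1 indicate BChE preference."""
    _check_positive(ki_ache=ki_ache, ki_bche=ki_bche)
    value = ki_ache / ki_bche
    return RatioEntry(label, numerator_id, denominator_id, value, round_ratio(value))


def stereoselectivity(
    ki_first: float,
    ki_second: float,
    label: str = "stereoselectivity",
    first_substituent: str | None = None,
    second_substituent: str | None = None,
) -> RatioEntry:
    """Ki ratio of a pseudo-enantiomeric pair (conventionally CN-type/CD-type).

    A ratio above 1 means the enzyme binds the denominator compound (the
    CD-type pseudo-enantiomer) more tightly.  When substituent codes are
    given for both compounds they must match.
    """
    _check_positive(ki_first=ki_first, ki_second=ki_second)
    if (
        first_substituent is not None
        and second_substituent is not None
        and first_substituent != second_substituent
    ):
        raise PairingError(
            f"mismatched substituent codes: {first_substituent!r} vs "
            f"{second_substituent!r}"
        )
    value = ki_first / ki_second
    return RatioEntry(
        label,
        first_substituent or "first",
        second_substituent or "second",
        value,
        round_ratio(value),
    )


def pair_pseudo_enantiomers(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match CN<->CD and DHCN<->DHCD rows on their substituent code.

    Returns ``(pairs, unmatched)``.  ``pairs`` has one row per matched pair
    with ``_cn``/``_cd`` suffixed Ki columns; unmatched rows are reported, not
    an error.  Duplicated (series, substituent) combinations are an invariant
    breach and raise :class:`PairingError`.
    """
    dupes = table.duplicated(subset=["series", "substituent"])
    if dupes.any():
        bad = table.loc[dupes, ["series", "substituent"]].to_records(index=False)
        raise PairingError(f"duplicated (series, substituent) rows: {list(bad)}")

    pairs, matched_idx = [], []
    for num_series, den_series in PSEUDO_ENANTIOMER_PAIRS.items():
        num = table[table["series"] == num_series]
        den = table[table["series"] == den_series]
        den_by_sub = {r.substituent: r for r in den.itertuples()}
        for r in num.itertuples():
            partner = den_by_sub.get(r.substituent)
            if partner is None:
                continue
            pairs.append(
                {
                    "pair": f"{num_series}/{den_series}",
                    "substituent": r.substituent,
                    "compound_cn": r.compound,
                    "compound_cd": partner.compound,
                    "Ki_BChE_cn": r.Ki_BChE_uM,
                    "Ki_BChE_cd": partner.Ki_BChE_uM,
                    "Ki_AChE_cn": r.Ki_AChE_uM,
                    "Ki_AChE_cd": partner.Ki_AChE_uM,
                }
            )
            matched_idx.extend([r.Index, partner.Index])
    pairs_df = pd.DataFrame(
        pairs,
        columns=[
            "pair", "substituent", "compound_cn", "compound_cd",
            "Ki_BChE_cn", "Ki_BChE_cd", "Ki_AChE_cn", "Ki_AChE_cd",
        ],
    )
    unmatched = table.drop(index=matched_idx)
    return pairs_df, unmatched


def ki_range(
    table: pd.DataFrame,
    enzyme: str,
    subset: pd.Series | None = None,
) -> tuple[float, float]:
    """(min, max) Ki in µM for ``enzyme`` over an optional boolean row subset."""
    if enzyme not in KI_COLUMNS:
        raise SarError(f"unknown enzyme {enzyme!r}; expected one of {list(KI_COLUMNS)}")
    values = table.loc[subset if subset is not None else slice(None), KI_COLUMNS[enzyme]]
    if len(values) == 0:
        raise SarError("empty selection for ki_range")
    return float(values.min()), float(values.max())


def selectivity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-compound SI table (raw and printed) from an activity table."""
    out = table[["compound", "series", "substituent"]].copy()
    entries = [
        selectivity_index(r.Ki_AChE_uM, r.Ki_BChE_uM, label=r.compound)
        for r in table.itertuples()
    ]
    out["SI"] = [e.value for e in entries]
    out["SI_printed"] = [e.printed_value for e in entries]
    return out


def stereoselectivity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format CN/CD and DHCN/DHCD Ki-ratio table for both enzymes."""
    pairs, _ = pair_pseudo_enantiomers(table)
    rows = []
    for r in pairs.itertuples():
        for enzyme, num, den in (
            ("BChE", r.Ki_BChE_cn, r.Ki_BChE_cd),
            ("AChE", r.Ki_AChE_cn, r.Ki_AChE_cd),
        ):
            entry = stereoselectivity(
                num, den, label=f"{r.pair} {r.substituent} {enzyme}",
                first_substituent=r.substituent, second_substituent=r.substituent,
            )
            rows.append(
                {
                    "pair": r.pair,
                    "substituent": r.substituent,
                    "enzyme": enzyme,
                    "ratio": entry.value,
                    "ratio_printed": entry.printed_value,
                }
            )
    return pd.DataFrame(rows)
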
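"""Enzyme-inhibitor dissociation constants from reversible-inhibition assays.

For a competitive, reversible inhibitor the apparent inhibition constant at a
single substrate concentration is

    Ki,app = vi * [I] / (v0 - vi)

where v0 and vi are the uninhibited and inhibited hydrolysis rates.  Plotting
Ki,app against the substrate concentration [S] gives the Hunter-Downs line

    Ki,app = K_I + (K_I / K_S) * S

whose intercept is the enzyme-inhibitor dissociation constant K_I and whose
slope encodes the enzyme-substrate dissociation constant K_S = intercept/slope.

Units are fixed by convention and never auto-converted: substrate in mM,
inhibitor and Ki in µM, rates in arbitrary (but mutually consistent) activity
units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KineticsError",
    "NoInhibitionError",
    "FullInhibitionError",
    "InsufficientDataError",
    "InhibitionRecord",
    "ApparentKiPoint",
    "KineticFit",
    "apparent_ki",
    "inhibition_fraction",
    "in_assay_window",
    "hunter_downs_fit",
    "fit_dataset",
    "read_assay_csv",
    "fit_assay_table",
]

logger = logging.getLogger(__name__)

#: Inclusive inhibition-fraction window used to select informative assay points.
ASSAY_WINDOW = (0.20, 0.80)

ASSAY_COLUMNS = ["compound", "enzyme", "substrate_mM", "inhibitor_uM", "v0", "vi"]


class KineticsError(ValueError):
    """Base class for kinetic-analysis errors."""


class NoInhibitionError(KineticsError):
    """Raised when the inhibited rate is not below the uninhibited rate."""


class FullInhibitionError(KineticsError):
    """Raised when the inhibited rate is zero or negative."""


class InsufficientDataError(KineticsError):
    """Raised when too few (or degenerate) points are available for a fit."""


@dataclass(frozen=True)
class InhibitionRecord:
    """One (S, I, v0, vi) assay observation.

    ``vi`` is allowed to violate 0 < vi < v0 at construction time so raw plate
    data can be loaded; :func:`apparent_ki` raises the specific error instead.
    """

    substrate_mM: float
    inhibitor_uM: float
    v0: float
    vi: float

    def __post_init__(self) -> None:
        if not self.substrate_mM > 0:
            raise KineticsError(f"substrate_mM must be > 0, got {self.substrate_mM}")
        if not self.inhibitor_uM > 0:
            raise KineticsError(f"inhibitor_uM must be > 0, got {self.inhibitor_uM}")
        if not self.v0 > 0:
            raise KineticsError(f"invalid record: v0 must be > 0, got {self.v0}")


@dataclass(frozen=True)
class ApparentKiPoint:
    """Apparent inhibition constant at one substrate concentration."""

    substrate_mM: float
    ki_app_uM: float


@dataclass(frozen=True)
class KineticFit:
    """Result of a Hunter-Downs regression.

    ``ki`` (µM) is the y-intercept; ``ks`` (mM) is intercept/slope and is
    ``None`` (with ``ks_suppressed``) when the slope is non-positive or
    numerically zero.  ``nonphysical`` flags a non-positive intercept.
    """

    ki: float
    ki_se: float
    slope: float
    slope_se: float
    ks: float | None
    r_squared: float
    n_points: int
    nonphysical: bool = False
    ks_suppressed: bool = False
    n_excluded: int = 0


def apparent_ki(record: InhibitionRecord) -> ApparentKiPoint:
    """Apparent Ki = vi * I / (v0 - vi) for a single assay observation."""
    if record.vi >= record.v0:
        raise NoInhibitionError(
            f"no inhibition: vi={record.vi} >= v0={record.v0}"
        )
    if record.vi <= 0:
        raise FullInhibitionError(f"full inhibition: vi={record.vi} <= 0")
    ki_app = record.vi * record.inhibitor_uM / (record.v0 - record.vi)
    return ApparentKiPoint(substrate_mM=record.substrate_mM, ki_app_uM=ki_app)


def inhibition_fraction(record: InhibitionRecord) -> float:
    """Fractional inhibition (v0 - vi) / v0."""
    return (record.v0 - record.vi) / record.v0


def in_assay_window(
    record: InhibitionRecord,
    window: tuple[float, float] = ASSAY_WINDOW,
) -> bool:
    """True when fractional inhibition lies in ``window`` (boundaries inclusive)."""
    lo, hi = window
    return lo <= inhibition_fraction(record) <= hi


def hunter_downs_fit(points: list[ApparentKiPoint] | tuple) -> KineticFit:
    """Unweighted OLS of Ki,app on S over all individual points.

    Requires at least three points spanning at least two distinct substrate
    concentrations.  Ks is reported as intercept/slope only when the slope is
    positive and not numerically degenerate.
    """
    points = list(points)
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 points for a Hunter-Downs fit, got {len(points)}"
        )
    s = np.asarray([p.substrate_mM for p in points], dtype=float)
    y = np.asarray([p.ki_app_uM for p in points], dtype=float)
    if np.unique(s).size < 2:
        raise InsufficientDataError("all substrate concentrations identical")

    res = stats.linregress(s, y)
    slope, intercept = float(res.slope), float(res.intercept)
    # y exactly constant: flat line is a perfect fit but rvalue is nan
    r2 = 1.0 if np.allclose(y, y[0]) else float(res.rvalue) ** 2

    ks_suppressed = not (slope > 1e-12)
    ks = None if ks_suppressed else intercept / slope
    return KineticFit(
        ki=intercept,
        ki_se=float(res.intercept_stderr),
        slope=slope,
        slope_se=float(res.stderr),
        ks=ks,
        r_squared=r2,
        n_points=len(points),
        nonphysical=not intercept > 0,
        ks_suppressed=ks_suppressed,
    )


def fit_dataset(
    records: list[InhibitionRecord],
    enforce_range: bool = True,
    window: tuple[float, float] = ASSAY_WINDOW,
) -> KineticFit:
    """Filter records, transform to apparent-Ki points and run the line fit.

    When ``enforce_range`` is on (the default), records outside the inclusive
    20-80 % inhibition window are excluded before fitting and the number of
    exclusions is logged and recorded on the result.
    """
    records = list(records)
    if not records:
        raise InsufficientDataError("empty record list")
    if enforce_range:
        kept = [r for r in records if in_assay_window(r, window)]
        n_excluded = len(records) - len(kept)
        if n_excluded:
            logger.info(
                "excluded %d/%d records outside %.0f-%.0f%% inhibition window",
                n_excluded, len(records), 100 * window[0], 100 * window[1],
            )
    else:
        kept, n_excluded = records, 0
    if not kept:
        raise InsufficientDataError("all records filtered out by inhibition window")
    fit = hunter_downs_fit([apparent_ki(r) for r in kept])
    return KineticFit(**{**fit.__dict__, "n_excluded": n_excluded})


def read_assay_csv(path) -> pd.DataFrame:
    """Read an assay CSV with header compound,enzyme,substrate_mM,inhibitor_uM,v0,vi."""
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise KineticsError(
            f"assay table missing column(s) {missing}; expected header "
            f"{','.join(ASSAY_COLUMNS)} (units are fixed: S in mM, I in µM)"
        )
    return df


def fit_assay_table(df: pd.DataFrame, enforce_range: bool = True) -> pd.DataFrame:
    """Fit every (compound, enzyme) group of an assay table.

    Returns a table with columns compound,enzyme,Ki_uM,Ki_se,Ks_mM,r2,n.
    """
    rows = []
    for (compound, enzyme), grp in df.groupby(["compound", "enzyme"], sort=True):
        records = [
            InhibitionRecord(r.substrate_mM, r.inhibitor_uM, r.v0, r.vi)
            for r in grp.itertuples()
        ]
        fit = fit_dataset(records, enforce_range=enforce_range)
        rows.append(
            {
                "compound": compound,
                "enzyme": enzyme,
                "Ki_uM": fit.ki,
                "Ki_se": fit.ki_se,
                "Ks_mM": fit.ks,
                "r2": fit.r_squared,
                "n": fit.n_points,
            }
        )
    return pd.DataFrame(rows)
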
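"""Synthetic data generators with known ground truth for every pipeline stage.

Every generator is a pure function of its spec (seed included).  The assay
simulator produces Ellman-style competitive-inhibition rates

    v0 = Vmax S / (Km + S),      vi = Vmax S / (Km (1 + I/Ki) + S)

with multiplicative log-normal noise (plate-reader-like, preserves rate
positivity); at zero noise the apparent inhibition constant obeys
Ki,app = Ki (1 + S/Km) exactly.  The activity-table generator draws Ki
log-uniformly over the dynamic ranges seen in quaternary Cinchona alkaloid
SAR panels (three orders of magnitude for BChE).  The fingerprint generator
plants a low-order polynomial link between a rank-3 latent space and an
activity response, so the PES-PCA + exhaustive-search pipeline has an exactly
known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefields import (
    DoubleWell2D,
    ForceField,
    HarmonicWell,
    LennardJones,
    ZeroField,
)
from .kinetics import InhibitionRecord

__all__ = [
    "AssaySimSpec",
    "FingerprintSimSpec",
    "simulate_assay",
    "default_inhibitor_levels",
    "inhibitor_for_fraction",
    "simulate_activity_table",
    "simulate_fingerprint_dataset",
    "toy_force_field",
    "TOY_FORCE_FIELDS",
]

# Assay design defaults: 9 substrate levels spanning 0.05-0.50 mM, at least
# three inhibitor concentrations, triplicate measurements.
DEFAULT_SUBSTRATE_GRID = tuple(np.round(np.linspace(0.05, 0.50, 9), 4))

# Ki dynamic ranges (µM) of the packaged activity tables.
DEFAULT_BCHE_RANGE = (0.075, 19.0)
DEFAULT_ACHE_RANGE = (3.9, 206.0)


@dataclass(frozen=True)
class AssaySimSpec:
    """Competitive-inhibition assay design with a known true Ki."""

    ki_true: float = 2.0            # µM
    km: float = 0.15                # mM
    vmax: float = 1.0
    substrate_grid: tuple = DEFAULT_SUBSTRATE_GRID
    inhibitor_levels: tuple | None = None   # µM; None -> 30/50/70 % targets
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ki_true <= 0 or self.km <= 0 or self.vmax <= 0:
            raise ValueError("ki_true, km and vmax must be positive")
        if not 0 <= self.noise_cv < 0.5:
            raise ValueError("noise_cv must be in [0, 0.5)")
        if self.replicates < 1 or len(self.substrate_grid) < 2:
            raise ValueError("need replicates >= 1 and >= 2 substrate levels")


def inhibitor_for_fraction(spec: AssaySimSpec, substrate_mM: float, fraction: float) -> float:
    """Inhibitor concentration (µM) giving a target inhibition fraction at S.

    From vi/v0 = (Km + S) / (Km (1 + I/Ki) + S) = 1 - f:
    I = Ki (Km + S) f / (Km (1 - f)).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return spec.ki_true * (spec.km + substrate_mM) * fraction / (spec.km * (1 - fraction))


def default_inhibitor_levels(
    spec: AssaySimSpec, window: tuple[float, float] = (0.20, 0.80), n_levels: int = 3
) -> tuple:
    """Inhibitor concentrations keeping every substrate level inside ``window``.

    For a fixed I the inhibition fraction f(S) = c / (Km + S + c) with
    c = Km I / Ki decreases with S, so the binding constraints are
    f(S_min) <= f_hi and f(S_max) >= f_lo.  Levels are spaced geometrically
    strictly inside the feasible c-interval; an infeasible window (possible
    for very wide substrate grids) falls back to targeting the window center
    at the median S.
    """
    f_lo, f_hi = window
    s_min, s_max = min(spec.substrate_grid), max(spec.substrate_grid)
    c_min = f_lo / (1 - f_lo) * (spec.km + s_max)
    c_max = f_hi / (1 - f_hi) * (spec.km + s_min)
    if c_min >= c_max:
        s_mid = float(np.median(spec.substrate_grid))
        mid = 0.5 * (f_lo + f_hi)
        return tuple(inhibitor_for_fraction(spec, s_mid, mid) for _ in range(1))
    c_levels = np.geomspace(c_min, c_max, n_levels + 2)[1:-1]
    return tuple(float(c) * spec.ki_true / spec.km for c in c_levels)


def _rates(spec: AssaySimSpec, s: float, i: float) -> tuple[float, float]:
    v0 = spec.vmax * s / (spec.km + s)
    vi = spec.vmax * s / (spec.km * (1 + i / spec.ki_true) + s)
    return v0, vi


def simulate_assay(spec: AssaySimSpec) -> list[InhibitionRecord]:
    """Simulate one inhibition assay; reproducible from ``spec.seed``.

    Inhibitor levels default to three concentrations chosen so that every
    noise-free record over the whole substrate grid falls inside the
    informative 20-80 % inhibition window (see
    :func:`default_inhibitor_levels`).
    Noise is multiplicative log-normal with mean 1 and CV ``noise_cv``,
    applied independently to v0 and vi.
    """
    rng = np.random.default_rng(spec.seed)
    levels = (
        default_inhibitor_levels(spec)
        if spec.inhibitor_levels is None
        else spec.inhibitor_levels
    )
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    records = []
    for s in spec.substrate_grid:
        for i in levels:
            for _ in range(spec.replicates):
                v0, vi = _rates(spec, float(s), float(i))
                if sigma > 0:
                    noise = np.exp(rng.normal(0.0, sigma, size=2) - 0.5 * sigma**2)
                    v0, vi = v0 * noise[0], vi * noise[1]
                records.append(InhibitionRecord(float(s), float(i), v0, vi))
    return records


def simulate_activity_table(
    n: int = 48,
    bche_range: tuple = DEFAULT_BCHE_RANGE,
    ache_range: tuple = DEFAULT_ACHE_RANGE,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-uniform Ki draws arranged as paired CN/CD pseudo-enantiomer rows.

    ``n`` compounds are produced as ceil(n/2) substituent codes, each with a
    CD-series and a CN-series row (the last code drops its CN partner when n
    is odd), so stereoselectivity pairing is always exercised.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    n_subs = (n + 1) // 2
    for j in range(n_subs):
        sub = f"sub{j:02d}"
        for series in ("CD", "CN"):
            if len(rows) == n:
                break
            kb = float(np.exp(rng.uniform(*np.log(bche_range))))
            ka = float(np.exp(rng.uniform(*np.log(ache_range))))
            rows.append(
                {
                    "compound": f"{series} {sub}",
                    "series": series,
                    "substituent": sub,
                    "Ki_BChE_uM": kb,
                    "Ki_BChE_se": 0.05 * kb,
                    "Ki_AChE_uM": ka,
                    "Ki_AChE_se": 0.05 * ka,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FingerprintSimSpec:
    """Planted-link generator for compound x fingerprint matrices.

    Latent scores Z are n x latent_rank standard normal; fingerprints are
    Z W' (W a fixed orthonormal q x latent_rank map) plus isotropic noise of
    scale ``fingerprint_noise_sd``; the response is the planted polynomial in
    the leading latent coordinates plus N(0, noise_sd) noise.
    """

    n_compounds: int = 24
    q: int = 64
    latent_rank: int = 3
    planted_terms: tuple = (((1, 0, 0), 1.0), ((0, 2, 0), -0.5))
    intercept: float = 2.0
    noise_sd: float = 0.01
    fingerprint_noise_sd: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank > self.q:
            raise ValueError("latent_rank must not exceed q")
        for exps, _coef in self.planted_terms:
            if len(exps) != self.latent_rank or sum(exps) < 1 or sum(exps) > 4:
                raise ValueError(
                    "planted terms must be exponent vectors over the latent "
                    "space with total degree 1..4"
                )


def simulate_fingerprint_dataset(
    spec: FingerprintSimSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (fingerprints, latent_scores, response) with known ground truth."""
    rng = np.random.default_rng(spec.seed)
    n, q, r = spec.n_compounds, spec.q, spec.latent_rank
    Z = rng.normal(size=(n, r))
    # fixed orthonormal map, deterministic given the seed
    W, _ = np.linalg.qr(rng.normal(size=(q, r)))
    F = Z @ W.T
    if spec.fingerprint_noise_sd > 0:
        F = F + rng.normal(0.0, spec.fingerprint_noise_sd, size=F.shape)
    y = np.full(n, spec.intercept)
    for exps, coef in spec.planted_terms:
        y = y + coef * np.prod(Z ** np.asarray(exps, dtype=float), axis=1)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    return F, Z, y


TOY_FORCE_FIELDS = ("harmonic", "lj_dimer", "lj_cluster", "double_well_2d", "zero")


def toy_force_field(name: str) -> ForceField:
    """Factory for the shipped analytic toy force fields."""
    if name == "harmonic":
        return HarmonicWell()
    if name in ("lj_dimer", "lj_cluster"):
        return LennardJones()
    if name == "double_well_2d":
        return DoubleWell2D()
    if name == "zero":
        return ZeroField()
    raise ValueError(f"unknown force field {name!r}; options: {TOY_FORCE_FIELDS}")
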
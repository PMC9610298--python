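"""Toy analytic force fields behind a pluggable evaluator contract.

A force field is any object with a ``name`` attribute and an
``evaluate(coords) -> (energy, gradient)`` method, where ``coords`` and the
gradient are (n, 3) arrays and forces are minus the gradient.  An adapter to
an external quantum-chemistry engine satisfies the same contract; the fields
shipped here keep every simulation self-contained and exactly differentiable,
which is what validating the sampling machinery requires.

All toy fields work in reduced units (k_B = 1).
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "ForceField",
    "HarmonicWell",
    "LennardJones",
    "DoubleWell2D",
    "ZeroField",
    "ShiftedField",
    "numerical_gradient",
]


@runtime_checkable
class ForceField(Protocol):
    """Evaluator contract: coordinates -> (potential energy, gradient)."""

    name: str

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]: ...


class HarmonicWell:
    """Isotropic harmonic well: E = (k/2) sum |r_i - c|^2."""

    def __init__(self, k: float = 1.0, center: np.ndarray | float = 0.0):
        self.k = float(k)
        self.center = np.asarray(center, dtype=float)
        self.name = "harmonic"

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.asarray(coords, dtype=float) - self.center
        return 0.5 * self.k * float(np.sum(d * d)), self.k * d


class LennardJones:
    """Pairwise 12-6 Lennard-Jones over all particle pairs (no cutoff).

    E = sum_{i<j} 4 eps [(sigma/r)^12 - (sigma/r)^6]; the minimum of a dimer
    sits at r = 2^(1/6) sigma with depth -eps.
    """

    def __init__(self, epsilon: float = 1.0, sigma: float = 1.0):
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.name = "lennard-jones"

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float)
        n = x.shape[0]
        energy = 0.0
        grad = np.zeros_like(x)
        with np.errstate(over="ignore", invalid="ignore"):
            return self._accumulate(x, n, energy, grad)

    def _accumulate(self, x, n, energy, grad):
        for i in range(n - 1):
            rij = x[i + 1:] - x[i]              # (n-i-1, 3)
            r2 = np.sum(rij * rij, axis=1)
            s2 = self.sigma**2 / r2
            s6 = s2**3
            energy += float(np.sum(4.0 * self.epsilon * (s6 * s6 - s6)))
            # dE/dr_j = 24 eps (s6 - 2 s12) / r^2 * r_ij
            coef = 24.0 * self.epsilon * (s6 - 2.0 * s6 * s6) / r2
            g = coef[:, None] * rij
            grad[i + 1:] += g
            grad[i] -= g.sum(axis=0)
        return energy, grad


class DoubleWell2D:
    """Quartic double well in x, harmonic in y and z, per particle.

    E = sum_i a (x_i^2 - b^2)^2 + (ky/2) y_i^2 + (kz/2) z_i^2, with minima at
    x = +/- b.
    """

    def __init__(self, a: float = 1.0, b: float = 1.0, ky: float = 1.0, kz: float = 1.0):
        self.a, self.b, self.ky, self.kz = map(float, (a, b, ky, kz))
        self.name = "double-well-2d"

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        r = np.asarray(coords, dtype=float)
        x, y, z = r[:, 0], r[:, 1], r[:, 2]
        q = x * x - self.b**2
        energy = float(np.sum(self.a * q * q + 0.5 * self.ky * y * y + 0.5 * self.kz * z * z))
        grad = np.empty_like(r)
        grad[:, 0] = 4.0 * self.a * q * x
        grad[:, 1] = self.ky * y
        grad[:, 2] = self.kz * z
        return energy, grad


class ZeroField:
    """Force-free field (uniform linear motion)."""

    name = "zero"

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return 0.0, np.zeros_like(np.asarray(coords, dtype=float))


class ShiftedField:
    """Wraps a field and adds a constant energy offset (gradient unchanged)."""

    def __init__(self, base: ForceField, offset: float):
        self.base = base
        self.offset = float(offset)
        self.name = f"{base.name}+{offset:g}"

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e, g = self.base.evaluate(coords)
        return e + self.offset, g


def numerical_gradient(field: ForceField, coords: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient, for validating analytic gradients."""
    x = np.asarray(coords, dtype=float)
    grad = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        grad[idx] = (field.evaluate(xp)[0] - field.evaluate(xm)[0]) / (2 * h)
    return grad
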
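"""Synthetic dissociation cases with known ground truth.

A :class:`SyntheticCase` fixes true Morse parameters, a true exponential
descriptor, a true entropy amplitude and a scan grid, and produces the same
tabular inputs a quantum-chemistry workflow would: an electronic dissociation
scan and a descriptor series, optionally with i.i.d. Gaussian noise.  The
default grid mirrors a typical relaxed-scan protocol with 0.05 Å steps from
just below the equilibrium distance out to 6 Å.

:func:`analytic_barrier` is a deliberately independent brute-force oracle: it
composes the exact free-energy curve from the TRUE parameters (no fitting)
and maximizes it on a dense grid, so pipeline results can be judged against
it.  Its formulas are written out locally rather than delegated to
:mod:`barrierless.core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scan_io import DescriptorSeries, DissociationScan


@dataclass
class SyntheticCase:
    """Ground truth of one synthetic dissociation.

    Energies in kJ/mol, distances in Å, decays in Å^-1.  ``amplitude`` is
    -T*(S_A + S_B - S_AB), negative when dissociation gains entropy.
    """

    well_depth: float = 20.0
    decay: float = 2.0
    r_eq: float = 1.95
    d0: float = 1.0
    k_desc: float = 1.5
    amplitude: float = -35.0
    noise_energy: float = 0.0       # sigma, kJ/mol
    noise_descriptor: float = 0.0   # sigma, dimensionless
    grid: tuple[float, float, float] = (1.90, 6.0, 0.05)  # r_start, r_end, step
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        r_start, r_end, step = self.grid
        if step <= 0 or r_end <= r_start:
            raise ValueError("grid must satisfy step > 0 and r_end > r_start")
        if r_start < self.r_eq - 0.2:
            raise ValueError("scan should not start more than 0.2 Å below r_eq")
        if self.noise_energy < 0 or self.noise_descriptor < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.well_depth <= 0 or self.decay <= 0 or self.d0 <= 0 or self.k_desc <= 0:
            raise ValueError("well_depth, decay, d0 and k_desc must be positive")

    @property
    def distances(self) -> np.ndarray:
        r_start, r_end, step = self.grid
        n = int(np.floor((r_end - r_start) / step + 1e-9)) + 1
        return r_start + step * np.arange(n)

    def morse_energy(self, r) -> np.ndarray:
        d = np.asarray(r, dtype=float) - self.r_eq
        return self.well_depth * (np.exp(-2 * self.decay * d)
                                  - 2 * np.exp(-self.decay * d))

    def descriptor_value(self, r) -> np.ndarray:
        return self.d0 * np.exp(-self.k_desc * np.asarray(r, dtype=float))


def gen_scan(case: SyntheticCase) -> DissociationScan:
    """Morse energies on the case grid plus Gaussian noise; seeded, reproducible."""
    r = case.distances
    e = case.morse_energy(r)
    if case.noise_energy > 0:
        rng = np.random.default_rng([case.seed, 0])
        e = e + rng.normal(0.0, case.noise_energy, size=r.size)
    return DissociationScan(r, e, label=case.label)


def gen_descriptor(case: SyntheticCase, name: str = "IBSI") -> DescriptorSeries:
    """Exponential descriptor on the case grid plus Gaussian noise, clipped >= 0."""
    r = case.distances
    v = case.descriptor_value(r)
    if case.noise_descriptor > 0:
        rng = np.random.default_rng([case.seed, 1])
        v = v + rng.normal(0.0, case.noise_descriptor, size=r.size)
    return DescriptorSeries(name, r, np.maximum(v, 0.0))


def grid_fit_exponential(r: np.ndarray, v: np.ndarray,
                         rounds: int = 7, points: int = 41) -> tuple[float, float]:
    """Least-squares fit of a*exp(-b*r) by iterative grid refinement.

    A derivative-free double implementation of the exponential fit: a
    log-linear seed, then ``rounds`` of a ``points`` x ``points`` grid search
    whose span shrinks tenfold around the running optimum.  Used by the
    brute-force oracle so it never shares an optimizer with the fitting code
    it checks.
    """
    mask = v > 1e-6
    slope, intercept = np.polyfit(r[mask], np.log(v[mask]), 1)
    a0, b0 = float(np.exp(intercept)), float(max(-slope, 1e-6))
    span_a, span_b = 0.8 * a0, 0.8 * b0
    shrunk = total = 0
    while shrunk < rounds and total < 200:
        total += 1
        aa = np.linspace(a0 - span_a, a0 + span_a, points)
        bb = np.linspace(max(b0 - span_b, 1e-9), b0 + span_b, points)
        pred = aa[:, None, None] * np.exp(-bb[None, :, None] * r[None, None, :])
        sse = np.sum((pred - v[None, None, :]) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        a0, b0 = float(aa[i]), float(bb[j])
        if 0 < i < points - 1 and 0 < j < points - 1:
            # optimum is interior: zoom in around it
            span_a *= 0.1
            span_b *= 0.1
            shrunk += 1
        # else: re-center on the edge hit and search again at the same span
    return a0, b0


def true_r_cleave(case: SyntheticCase, gamma_cleave: float) -> float:
    """Cleavage distance implied by the TRUE (noiseless) descriptor.

    Min-max normalization over the finite grid shifts the exponential by its
    small tail value, so the normalized series is not exactly
    d0'*exp(-k*r); its least-squares exponential representation (computed
    here by an independent grid search) defines the cleavage distance, to
    which the slope cutoff is applied in closed form.
    """
    r = case.distances
    v = case.descriptor_value(r)
    vn = (v - v.min()) / (v.max() - v.min())
    d0n, kn = grid_fit_exponential(r, vn)
    return math.log(kn * d0n / gamma_cleave) / kn


def analytic_barrier(case: SyntheticCase, gamma_cleave: float, k_sig: float,
                     grid_step: float = 1e-4,
                     tol_barrier: float = 0.01) -> float | None:
    """Brute-force dissociation barrier from the TRUE parameters.

    Composes dG(r) = Morse(r) + amplitude/(1 + exp(-k_sig (r - r_cleave)))
    exactly, maximizes it on a ``grid_step`` grid over
    [r_eq, max(r_end, r_cleave + 10/k_sig)], and returns the barrier
    dG_max - dG(r_eq), or None if the curve has no interior maximum exceeding
    either reference (the no-barrier outcome).
    """
    rc = true_r_cleave(case, gamma_cleave)
    r_lo = case.r_eq
    r_hi = max(case.grid[1], rc + 10.0 / k_sig)
    n = int(math.ceil((r_hi - r_lo) / grid_step)) + 1
    r = np.linspace(r_lo, r_hi, n)
    g = case.morse_energy(r) + case.amplitude / (
        1.0 + np.exp(-k_sig * (r - rc)))
    g_req = float(g[0])
    i = int(np.argmax(g[1:-1])) + 1
    if g[i] < g[0] or g[i] < g[-1]:
        return None
    g_max = float(g[i])
    if g_max - g_req <= tol_barrier and g_max - case.amplitude <= tol_barrier:
        return None
    return g_max - g_req


def random_case(rng: np.random.Generator, noise_energy: float = 0.0,
                noise_descriptor: float = 0.0) -> SyntheticCase:
    """Draw a plausible dissociation: tens-of-kJ/mol well, descriptor decaying
    over the scan range, entropy amplitude in the typical -20..-50 kJ/mol band."""
    r_eq = float(rng.uniform(1.7, 2.2))
    return SyntheticCase(
        well_depth=float(rng.uniform(15.0, 60.0)),
        decay=float(rng.uniform(1.8, 3.0)),
        r_eq=r_eq,
        d0=float(rng.uniform(0.5, 2.0)),
        k_desc=float(rng.uniform(1.0, 1.8)),
        amplitude=float(rng.uniform(-50.0, -20.0)),
        noise_energy=noise_energy,
        noise_descriptor=noise_descriptor,
        grid=(round(r_eq - 0.05, 3), 6.0, 0.05),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
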
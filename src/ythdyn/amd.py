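"""Accelerated-MD boost potential, parameter heuristics, toy Langevin
sampler, and free-energy reweighting.

Accelerated MD (aMD) flattens a potential-energy surface by adding a boost

    dV(r) = (E - V(r))^2 / (alpha + E - V(r))      whenever V(r) < E,

and leaving the potential untouched above the threshold ``E``; ``alpha``
controls how aggressively low-energy regions are raised.  Canonical
statistics are recovered afterwards by weighting each stored frame with
``exp(beta * dV)`` (or a Maclaurin expansion of it, which trades bias for
variance when ``beta * dV`` is large).

The dual-boost convention applies one boost to the dihedral term and a second
to the (already dihedral-boosted) total potential.  Thresholds and
acceleration factors are conventionally estimated from a short conventional
MD run via linear heuristics in the atom and residue counts; see
:func:`estimate_amd_parameters`.

The module also ships a small Langevin (BAOAB) sampler for analytic toy
potentials so the boost/reweight machinery can be validated against exact
quadrature on a desk scale.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "KB_KCAL",
    "KCAL_PER_INTERNAL",
    "ThermoState",
    "ParameterCoefficients",
    "AMDParameters",
    "ToySystem",
    "BoostedTrajectory",
    "FreeEnergySurface",
    "boost_delta_v",
    "boosted_force_factor",
    "dual_boost",
    "estimate_amd_parameters",
    "run_langevin",
    "reweight",
    "fes",
    "basin_barrier",
    "count_transitions",
]

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041
#: 1 kcal mol^-1 expressed in amu Angstrom^2 ps^-2 (the integrator's units).
KCAL_TO_INTERNAL = 418.4
KCAL_PER_INTERNAL = 1.0 / KCAL_TO_INTERNAL


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived inverse temperature (kcal mol^-1)."""

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


@dataclass(frozen=True)
class ParameterCoefficients:
    """Linear heuristics for aMD thresholds/acceleration factors.

    Units: ``per_atom_E`` and ``per_atom_alpha`` in kcal mol^-1 atom^-1,
    ``per_residue_E`` in kcal mol^-1 residue^-1; ``dihedral_alpha_fraction``
    is dimensionless.
    """

    per_atom_E: float = 0.16
    per_atom_alpha: float = 0.2
    per_residue_E: float = 3.5
    dihedral_alpha_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("per_atom_E", "per_atom_alpha", "per_residue_E",
                     "dihedral_alpha_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AMDParameters:
    """Dual-boost thresholds and acceleration factors (kcal mol^-1)."""

    E_tot: float
    alpha_tot: float
    E_dih: float
    alpha_dih: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha_tot <= 0 or self.alpha_dih <= 0:
            raise ValueError("acceleration factors must be positive")
        for v in (self.E_tot, self.alpha_tot, self.E_dih, self.alpha_dih):
            if not math.isfinite(v):
                raise ValueError("aMD parameters must be finite")

    def report(self) -> dict[str, int]:
        """Nearest-integer values, the convention used when quoting them."""
        return {
            "E_tot": round(self.E_tot),
            "alpha_tot": round(self.alpha_tot),
            "E_dih": round(self.E_dih),
            "alpha_dih": round(self.alpha_dih),
        }


def estimate_amd_parameters(
    mean_V_tot: float,
    mean_V_dih: float,
    n_atoms: int,
    n_residues: int,
    coeffs: ParameterCoefficients = ParameterCoefficients(),
) -> AMDParameters:
    """Dual-boost parameters from conventional-MD averages and system size.

    ``E_tot = <V_tot> + per_atom_E * n_atoms``;
    ``alpha_tot = per_atom_alpha * n_atoms``;
    ``E_dih = <V_dih> + per_residue_E * n_residues``;
    ``alpha_dih = dihedral_alpha_fraction * per_residue_E * n_residues``.

    ``n_atoms`` is taken verbatim (it typically includes solvent atoms);
    ``n_residues`` counts solute residues plus nucleotides.  Full precision is
    retained internally; round only when reporting (:meth:`AMDParameters.report`).
    """
    if n_atoms < 1 or n_residues < 1:
        raise ValueError("atom and residue counts must be positive")
    return AMDParameters(
        E_tot=mean_V_tot + coeffs.per_atom_E * n_atoms,
        alpha_tot=coeffs.per_atom_alpha * n_atoms,
        E_dih=mean_V_dih + coeffs.per_residue_E * n_residues,
        alpha_dih=coeffs.dihedral_alpha_fraction * coeffs.per_residue_E * n_residues,
        provenance={
            "mean_V_tot": mean_V_tot,
            "mean_V_dih": mean_V_dih,
            "n_atoms": n_atoms,
            "n_residues": n_residues,
        },
    )


# ---------------------------------------------------------------------------
# Boost potential
# ---------------------------------------------------------------------------

def boost_delta_v(V, E: float, alpha: float):
    """Boost energy dV = (E-V)^2/(alpha+E-V) below threshold, 0 at/above it."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = np.asarray(V, dtype=float)
    gap = E - V
    with np.errstate(divide="ignore", invalid="ignore"):
        boosted = gap * gap / (alpha + gap)
    out = np.where(gap > 0, boosted, 0.0)
    return float(out) if out.ndim == 0 else out


def boosted_force_factor(V, E: float, alpha: float):
    """d(V + dV)/dV: 1 at/above the threshold, (alpha/(alpha+E-V))^2 below.

    This is the factor by which forces are scaled on the boosted surface; it
    lies in (0, 1] and is continuous at V = E.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = np.asarray(V, dtype=float)
    gap = E - V
    factor = np.where(gap > 0, (alpha / (alpha + np.maximum(gap, 0.0))) ** 2, 1.0)
    return float(factor) if factor.ndim == 0 else factor


def dual_boost(V_dih, V_tot, params: AMDParameters):
    """Dual-boost energies: dihedral boost first, then the total-potential
    boost evaluated on the dihedral-boosted total.

    Returns ``(dV_dih, dV_tot)``; the frame's reweighting energy is their sum.
    """
    dV_dih = boost_delta_v(V_dih, params.E_dih, params.alpha_dih)
    dV_tot = boost_delta_v(np.asarray(V_tot) + dV_dih, params.E_tot, params.alpha_tot)
    return dV_dih, dV_tot


# ---------------------------------------------------------------------------
# Toy systems and Langevin sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySystem:
    """Analytic toy potential for desk-scale validation.

    ``double_well``: U(x) = h (x^2 - 1)^2 + tilt * x (1D; minima near +-1,
    barrier height ~h at x = 0 for tilt = 0).
    ``double_basin_2d``: the same along x plus a harmonic y-channel
    0.5 * k_transverse * y^2.

    ``mass`` (amu) and ``friction`` (ps^-1) parameterise the Langevin bath.
    """

    potential: str = "double_well"
    barrier_height: float = 3.0       # h, kcal mol^-1
    tilt: float = 0.0                 # kcal mol^-1 per Angstrom
    k_transverse: float = 2.0         # kcal mol^-1 per Angstrom^2 (2D only)
    mass: float = 12.0
    friction: float = 1.0

    def __post_init__(self) -> None:
        if self.potential not in ("double_well", "double_basin_2d"):
            raise ValueError(f"unknown toy potential {self.potential!r}")
        if self.barrier_height <= 0:
            raise ValueError("barrier height h must be positive")

    @property
    def dimension(self) -> int:
        return 1 if self.potential == "double_well" else 2

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = self.barrier_height
        u = h * (x[:, 0] ** 2 - 1.0) ** 2 + self.tilt * x[:, 0]
        if self.dimension == 2:
            u = u + 0.5 * self.k_transverse * x[:, 1] ** 2
        return u

    def force(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = self.barrier_height
        f = np.zeros_like(x)
        f[:, 0] = -4.0 * h * x[:, 0] * (x[:, 0] ** 2 - 1.0) - self.tilt
        if self.dimension == 2:
            f[:, 1] = -self.k_transverse * x[:, 1]
        return f


@dataclass
class BoostedTrajectory:
    """Positions with per-frame potential energy and boost energy."""

    samples: np.ndarray          # F x d
    V: np.ndarray                # kcal mol^-1, unboosted potential
    deltaV: np.ndarray           # kcal mol^-1, >= 0; 0 wherever V >= E
    seed: int
    params: AMDParameters | None = None

    def __post_init__(self) -> None:
        if np.any(self.deltaV < 0):
            raise ValueError("boost energies must be non-negative")


class DivergenceError(RuntimeError):
    """Integrator left the guard radius; dt too large or potential unbounded."""


def run_langevin(
    system: ToySystem,
    thermo: ThermoState,
    n_samples: int,
    dt: float = 0.002,
    stride: int = 10,
    seed: int = 0,
    params: AMDParameters | None = None,
    x0: np.ndarray | None = None,
    guard_radius: float = 25.0,
    n_equil_steps: int = 2000,
) -> BoostedTrajectory:
    """Sample a toy potential with BAOAB Langevin dynamics.

    When ``params`` is given the forces are scaled by the boosted force
    factor of the *total* channel (analytic toys have no dihedral term, so the
    dihedral channel is unused) and the per-frame boost energy is recorded for
    reweighting.  ``dt`` is in ps; samples are stored every ``stride`` steps
    after ``n_equil_steps`` equilibration steps.  Stability requires
    ``dt * sqrt(U''/m)`` well below 1; the defaults (dt 2 fs, mass 12 amu)
    satisfy this for barrier heights up to ~10 kcal mol^-1.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if dt <= 0 or stride < 1:
        raise ValueError("dt must be positive and stride >= 1")
    # Stability guard against the stiffest curvature of the double well.
    omega = math.sqrt(8.0 * system.barrier_height * KCAL_TO_INTERNAL / system.mass)
    if dt * max(omega, system.friction) > 0.5:
        raise ValueError(
            f"dt={dt} ps unstable for this system (omega={omega:.1f} ps^-1)"
        )

    rng = np.random.default_rng(seed)
    d = system.dimension
    x = np.zeros((1, d)) if x0 is None else np.atleast_2d(np.asarray(x0, float))
    if x0 is None:
        x[0, 0] = -1.0  # start in the left basin
    m = system.mass
    kT_int = thermo.kT * KCAL_TO_INTERNAL
    v = rng.normal(0.0, math.sqrt(kT_int / m), size=(1, d))
    c1 = math.exp(-system.friction * dt)
    c2 = math.sqrt(kT_int / m * (1.0 - c1 * c1))

    def boosted_force(pos: np.ndarray) -> np.ndarray:
        f = system.force(pos) * KCAL_TO_INTERNAL  # internal units
        if params is not None:
            factor = boosted_force_factor(system.energy(pos), params.E_tot,
                                          params.alpha_tot)
            f = f * np.asarray(factor)[:, None]
        return f

    samples = np.empty((n_samples, d))
    V = np.empty(n_samples)
    dV = np.empty(n_samples)
    f = boosted_force(x)
    total_steps = n_equil_steps + n_samples * stride
    taken = 0
    for step in range(total_steps):
        v = v + (0.5 * dt / m) * f
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=(1, d))
        x = x + 0.5 * dt * v
        f = boosted_force(x)
        v = v + (0.5 * dt / m) * f
        if np.any(np.abs(x) > guard_radius):
            raise DivergenceError(
                f"position {x.ravel()} left guard radius {guard_radius} at "
                f"step {step}; reduce dt or check the potential"
            )
        if step >= n_equil_steps and (step - n_equil_steps) % stride == stride - 1:
            energy = float(system.energy(x)[0])
            samples[taken] = x[0]
            V[taken] = energy
            dV[taken] = (
                boost_delta_v(energy, params.E_tot, params.alpha_tot)
                if params is not None
                else 0.0
            )
            taken += 1
    return BoostedTrajectory(samples=samples, V=V, deltaV=dV, seed=seed,
                             params=params)


# ---------------------------------------------------------------------------
# Reweighting and free-energy surfaces
# ---------------------------------------------------------------------------

def reweight(
    deltaV: np.ndarray,
    thermo: ThermoState,
    method: str = "exponential",
    order: int = 10,
) -> np.ndarray:
    """Canonical frame weights from per-frame boost energies.

    ``exponential``: w_i proportional to exp(beta * dV_i), computed with the
    maximum subtracted before exponentiation so large boosts cannot overflow.
    ``maclaurin``: w_i proportional to the order-``order`` Maclaurin partial
    sum of the exponential, a lower-variance (but biased) estimator popular
    when beta*dV is large.  Weights are normalised to sum to one.
    """
    dv = np.asarray(deltaV, dtype=float)
    if np.any(dv < 0):
        raise ValueError("boost energies must be non-negative")
    b_dv = thermo.beta * dv
    if method == "exponential":
        w = np.exp(b_dv - b_dv.max())
    elif method == "maclaurin":
        if order < 1:
            raise ValueError("maclaurin order must be >= 1")
        w = np.zeros_like(b_dv)
        term = np.ones_like(b_dv)
        w += term
        for j in range(1, order + 1):
            term = term * b_dv / j
            w += term
    else:
        raise ValueError(f"unknown reweighting method {method!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate weights (all zero)")
    return w / total


@dataclass
class FreeEnergySurface:
    """Binned free energies, min-shifted to zero; empty bins are +inf."""

    bin_edges: list[np.ndarray]
    free_energy: np.ndarray       # kcal mol^-1
    counts: np.ndarray
    weight_sums: np.ndarray

    @property
    def bin_centers(self) -> list[np.ndarray]:
        return [0.5 * (e[:-1] + e[1:]) for e in self.bin_edges]

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def fes(
    samples: np.ndarray,
    thermo: ThermoState,
    weights: np.ndarray | None = None,
    bins: int | list = 40,
    range_: list[tuple[float, float]] | None = None,
) -> FreeEnergySurface:
    """Weighted free-energy surface G = -kT ln(density), min-shifted to 0.

    ``samples`` is F x d (toy positions or PCA projections); uniform weights
    are assumed when ``weights`` is omitted.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != n:
        raise ValueError("weights length must match sample count")
    wsum, edges = np.histogramdd(samples, bins=bins, range=range_, weights=weights)
    counts, _ = np.histogramdd(samples, bins=edges)
    if np.count_nonzero(counts) <= 1:
        import warnings

        warnings.warn("degenerate free-energy surface: all samples in one bin",
                      stacklevel=2)
    with np.errstate(divide="ignore"):
        G = np.where(wsum > 0, -thermo.kT * np.log(np.maximum(wsum, 1e-300)), np.inf)
    G = G - G[np.isfinite(G)].min()
    return FreeEnergySurface(bin_edges=list(edges), free_energy=G,
                             counts=counts, weight_sums=wsum)


def _region_mask(surface: FreeEnergySurface, region) -> np.ndarray:
    """A bin region given as a boolean mask, or per-dimension (lo, hi) bounds
    in coordinate units (bin membership decided by bin centers)."""
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != surface.free_energy.shape:
            raise ValueError("region mask shape mismatch")
        return region
    bounds = region
    if np.ndim(bounds) == 1:
        bounds = [tuple(bounds)]
    centers = surface.bin_centers
    mask = np.ones(surface.free_energy.shape, dtype=bool)
    for dim, (lo, hi) in enumerate(bounds):
        axis_in = (centers[dim] >= lo) & (centers[dim] <= hi)
        shape = [1] * surface.free_energy.ndim
        shape[dim] = -1
        mask &= axis_in.reshape(shape)
    return mask


def basin_barrier(
    surface: FreeEnergySurface,
    basin_a,
    basin_b,
) -> tuple[float, float]:
    """Free-energy difference and forward barrier between two basins.

    ``deltaG = G_min(basin_b) - G_min(basin_a)``.  The barrier is the minimax
    path value between the two basin minima over the binned surface (the
    lowest saddle reachable through face-adjacent occupied bins), measured
    from basin a's minimum.  Swapping the basins flips the sign of deltaG and
    recomputes the barrier from the other minimum.
    """
    G = surface.free_energy
    mask_a = _region_mask(surface, basin_a)
    mask_b = _region_mask(surface, basin_b)
    if np.any(mask_a & mask_b):
        raise ValueError("basin regions must be disjoint")
    for name, mask in (("a", mask_a), ("b", mask_b)):
        if not np.any(np.isfinite(G[mask])):
            raise ValueError(f"basin {name} contains no occupied bins")

    def _argmin(mask: np.ndarray) -> tuple[int, ...]:
        masked = np.where(mask, G, np.inf)
        return np.unravel_index(np.argmin(masked), G.shape)

    start = _argmin(mask_a)
    goal = _argmin(mask_b)
    delta_g = float(G[goal] - G[start])

    # Minimax (lowest-saddle) path over face-adjacent occupied bins.
    shape = G.shape
    best = np.full(shape, np.inf)
    best[start] = G[start]
    heap = [(G[start], start)]
    offsets = []
    for dim in range(G.ndim):
        for step in (-1, 1):
            off = [0] * G.ndim
            off[dim] = step
            offsets.append(tuple(off))
    while heap:
        ceil, idx = heapq.heappop(heap)
        if idx == goal:
            return delta_g, float(ceil - G[start])
        if ceil > best[idx]:
            continue
        for off in offsets:
            nxt = tuple(i + o for i, o in zip(idx, off))
            if any(i < 0 or i >= s for i, s in zip(nxt, shape)):
                continue
            if not np.isfinite(G[nxt]):
                continue
            cand = max(ceil, G[nxt])
            if cand < best[nxt]:
                best[nxt] = cand
                heapq.heappush(heap, (cand, nxt))
    raise ValueError("basins are not connected through occupied bins")


def count_transitions(x: np.ndarray, lower: float = -0.5,
                      upper: float = 0.5) -> int:
    """Count well-to-well crossings of a 1D series with hysteresis.

    A transition is registered each time the series, last seen at or below
    ``lower``, reaches ``upper`` (or vice versa); excursions that do not reach
    the opposite threshold are not counted.
    """
    x = np.asarray(x, dtype=float).ravel()
    state = 0  # -1 left, +1 right, 0 undecided
    n = 0
    for xi in x:
        if xi <= lower:
            if state == 1:
                n += 1
            state = -1
        elif xi >= upper:
            if state == -1:
                n += 1
            state = 1
    return n
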
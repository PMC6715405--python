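"""Deterministic reference integrator for the activator-substrate PDEs.

The mean-field limit of the HB reaction set is the Gray-Scott /
Schnakenberg pair::

    d[H]/dt = D_H lap[H] + k1 [H]^2 [B] + k4 - k5 [H]
    d[B]/dt = D_B lap[B] - k1 [H]^2 [B] + k2 - k3 [B]

discretized on the same voxel lattice as the stochastic engine with a
5-point (2D) or 7-point (3D) Laplacian and zero-flux boundaries
(missing neighbors are simply absent, which makes the discrete
Laplacian conservative). Time stepping is explicit Euler under the
standard stability bound ``dt < 1 / (2 d max(D))``.

This module serves as the deterministic oracle for the stochastic
engine: single-voxel trajectories agree with the chemical master
equation's mean at large copy numbers, and the linear-stability
dispersion relation predicts whether the matched stochastic run will
form supra-threshold spots (a Turing band) or stay spatially noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .geometry import LatticeGeometry

__all__ = [
    "ContinuousField",
    "hb_reaction_terms",
    "integrate",
    "integrate_single_voxel",
    "homogeneous_steady_state",
    "dispersion_relation",
    "laplacian_matrix",
]


class IntegrationError(RuntimeError):
    """The explicit scheme produced a NaN or negative concentration."""


@dataclass
class ContinuousField:
    """Real-valued concentrations of H and B on a lattice geometry."""

    geometry: LatticeGeometry
    H: np.ndarray
    B: np.ndarray
    time: float = 0.0

    def copy(self) -> "ContinuousField":
        return replace(self, H=self.H.copy(), B=self.B.copy())

    @classmethod
    def uniform(cls, geometry, H0: float, B0: float) -> "ContinuousField":
        n = geometry.n_voxels
        return cls(geometry, np.full(n, float(H0)), np.full(n, float(B0)))

    def perturbed(self, amplitude: float = 0.01,
                  rng: np.random.Generator | None = None) -> "ContinuousField":
        """Multiplicative uniform noise of the given relative amplitude.

        Deterministic runs need an explicit perturbation to break the
        symmetry of the homogeneous steady state (the SSA has intrinsic
        noise; the PDE does not).
        """
        rng = rng or np.random.default_rng(0)
        f = self.copy()
        f.H *= 1.0 + amplitude * (2.0 * rng.random(f.H.size) - 1.0)
        f.B *= 1.0 + amplitude * (2.0 * rng.random(f.B.size) - 1.0)
        return f


def laplacian_matrix(geometry: LatticeGeometry) -> sp.csr_matrix:
    """Sparse graph Laplacian of the face-adjacency with zero-flux edges.

    Row i holds +1 for each in-domain neighbor and -deg(i) on the
    diagonal, so row sums vanish and total mass is conserved.
    """
    nbrs = geometry.neighbors
    rows, cols = np.nonzero(nbrs >= 0)
    data = np.ones(rows.size)
    lap = sp.coo_matrix((data, (rows, nbrs[rows, cols])),
                        shape=(geometry.n_voxels, geometry.n_voxels))
    lap = lap.tocsr()
    lap = lap - sp.diags(np.asarray(lap.sum(axis=1)).ravel())
    return lap.tocsr()


def hb_reaction_terms(H, B, params):
    """Reaction parts of the activator-substrate pair (no diffusion)."""
    k1, k2, k3 = params["k1"], params["k2"], params["k3"]
    k4, k5 = params["k4"], params["k5"]
    auto = k1 * H * H * B
    return auto + k4 - k5 * H, -auto + k2 - k3 * B


def _check_dt(dt, params, dim):
    dmax = max(params.get("D_H", 0.0), params.get("D_B", 0.0))
    if dmax > 0 and not dt < 1.0 / (2.0 * dim * dmax):
        raise ValueError(
            f"dt={dt} violates the explicit stability bound "
            f"1/(2*{dim}*{dmax}) = {1.0 / (2 * dim * dmax):.3g}")


def integrate(fields: ContinuousField, params: dict, dt: float,
              n_steps: int) -> ContinuousField:
    """Advance the activator-substrate pair by ``n_steps`` Euler steps.

    ``params`` holds ``k1..k5, D_H, D_B``. Raises
    :class:`IntegrationError` (with the step index) on NaN or negative
    concentrations rather than clipping: a negative value means the
    dt/parameter regime is invalid and clipping would silently distort
    the dynamics.
    """
    if dt <= 0 or n_steps < 0:
        raise ValueError("dt must be > 0 and n_steps >= 0")
    geom = fields.geometry
    _check_dt(dt, params, geom.dimensionality)
    lap = laplacian_matrix(geom)
    DH, DB = params.get("D_H", 0.0), params.get("D_B", 0.0)
    H = fields.H.astype(np.float64).copy()
    B = fields.B.astype(np.float64).copy()
    for step in range(int(n_steps)):
        fH, fB = hb_reaction_terms(H, B, params)
        H += dt * (DH * lap.dot(H) + fH)
        B += dt * (DB * lap.dot(B) + fB)
        if not (np.isfinite(H).all() and np.isfinite(B).all()):
            raise IntegrationError(f"non-finite concentration at step {step}")
        if (H < 0).any() or (B < 0).any():
            raise IntegrationError(f"negative concentration at step {step}")
    return ContinuousField(geom, H, B, fields.time + dt * int(n_steps))


def integrate_single_voxel(H0, B0, params, t_end, rtol=1e-10, atol=1e-12):
    """High-accuracy ODE solve of the reaction terms alone (no diffusion).

    Independent oracle for both the Euler integrator and the large-count
    mean of the single-voxel SSA. Uses an adaptive Runge-Kutta (DOP853).
    """
    from scipy.integrate import solve_ivp

    def rhs(_t, y):
        fH, fB = hb_reaction_terms(y[0], y[1], params)
        return [fH, fB]

    sol = solve_ivp(rhs, (0.0, t_end), [H0, B0], method="DOP853",
                    rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise IntegrationError(sol.message)
    return sol


def homogeneous_steady_state(params: dict) -> list:
    """All non-negative homogeneous steady states ``([H]*, [B]*)``.

    Eliminating B from the fixed-point equations gives a cubic in H:
    ``-k5 k1 H^3 + k1 (k2 + k4) H^2 - k5 k3 H + k4 k3 = 0``; B follows
    as ``k2 / (k3 + k1 H^2)``. Roots are found numerically and verified
    by residual; states are returned sorted by [H]*.
    """
    k1, k2, k3 = params["k1"], params["k2"], params["k3"]
    k4, k5 = params["k4"], params["k5"]
    if k5 <= 0 or k3 < 0:
        raise ValueError("require k5 > 0 and k3 >= 0")
    if k1 == 0:
        if k3 == 0:
            raise ValueError("k1 = k3 = 0 leaves B without a steady state")
        return [(k4 / k5, k2 / k3)]
    roots = np.roots([-k5 * k1, k1 * (k2 + k4), -k5 * k3, k4 * k3])
    out = []
    for r in roots:
        if abs(r.imag) > 1e-9 * max(1.0, abs(r.real)):
            continue
        H = float(r.real)
        if H < -1e-12:
            continue
        H = max(H, 0.0)
        denom = k3 + k1 * H * H
        if denom <= 0:
            continue
        B = k2 / denom
        fH, fB = hb_reaction_terms(H, B, params)
        scale = max(1.0, abs(k2), abs(k4), k5 * H)
        if abs(fH) < 1e-8 * scale and abs(fB) < 1e-8 * scale:
            out.append((H, B))
    if not out:
        raise ValueError("no non-negative homogeneous steady state found")
    out.sort()
    # de-duplicate near-identical roots
    dedup = [out[0]]
    for h, b in out[1:]:
        if abs(h - dedup[-1][0]) > 1e-8 * max(1.0, h):
            dedup.append((h, b))
    return dedup


def jacobian(steady_state, params) -> np.ndarray:
    """Reaction Jacobian at a homogeneous steady state."""
    H, B = steady_state
    k1, k3, k5 = params["k1"], params["k3"], params["k5"]
    return np.array([
        [2.0 * k1 * H * B - k5, k1 * H * H],
        [-2.0 * k1 * H * B, -k3 - k1 * H * H],
    ])


def dispersion_relation(params: dict, steady_state, wavenumbers) -> dict:
    """Linear growth rate of spatial mode q for each wavenumber.

    For each q, the leading eigenvalue (largest real part) of
    ``J - q^2 diag(D_H, D_B)`` is reported. A contiguous set of q with
    positive growth rate is the Turing band: the homogeneous state is
    unstable to patterns at those wavelengths, and the matched
    stochastic run is expected to form persistent spots with spacing
    near ``2 pi / q_max``.
    """
    q = np.asarray(wavenumbers, dtype=np.float64)
    J = jacobian(steady_state, params)
    D = np.diag([params.get("D_H", 0.0), params.get("D_B", 0.0)])
    growth = np.empty(q.size)
    for i, qi in enumerate(q):
        growth[i] = np.linalg.eigvals(J - qi * qi * D).real.max()
    unstable = q[growth > 0]
    band = (float(unstable.min()), float(unstable.max())) if unstable.size \
        else None
    i_max = int(np.argmax(growth))
    return {
        "wavenumbers": q,
        "growth_rates": growth,
        "unstable_band": band,
        "q_max": float(q[i_max]),
        "max_growth_rate": float(growth[i_max]),
        "has_turing_band": bool(band is not None and growth[0] <= 0),
    }
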
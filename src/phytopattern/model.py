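"""Homogeneous states and linear stability of the local phytomass model.

The model describes the areal density of perennial-grass biomass
:math:`\\rho(\\mathbf{r}, t)` on bare soil through a local
interaction–redistribution equation,

.. math::

    \\partial_t \\rho = -\\rho\\,(\\eta - \\kappa\\rho + \\rho^2)
        + (\\Delta - \\Gamma\\rho)\\,\\nabla^2\\rho
        - \\alpha\\,\\rho\\,\\nabla^4\\rho ,

where ``eta`` is the aridity (death-to-growth ratio), ``kappa`` measures
the balance of short-range facilitation against longer-range root
competition, and ``delta``, ``gamma_nl`` and ``alpha_nl`` control the
linear and biomass-dependent parts of the seed/clonal redistribution.
The biomass-dependent diffusivities make the dynamics nonvariational:
there is no free energy decreasing along trajectories.

This module provides the kinetics, the homogeneous steady states and
their fold (limit point), the dispersion relation about a uniform state,
and the finite-wavenumber (Turing) instability thresholds.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "SteadyStateSet",
    "DispersionResult",
    "kinetics",
    "kinetics_derivative",
    "homogeneous_states",
    "limit_point",
    "dispersion_relation",
    "critical_wavenumber",
    "turing_threshold",
    "bifurcation_diagram",
]

#: absolute tolerance used to accept "rho is a steady state" arguments
STEADY_STATE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """The five control parameters of the phytomass equation.

    Parameters
    ----------
    eta : float
        Aridity parameter, the ratio of biomass decrease to growth rates.
        Strictly positive: higher values mean harsher conditions.
    kappa : float
        Facilitation-to-competition susceptibility ratio.  For
        ``kappa > 0`` a pair of vegetated uniform branches exists below
        the fold at ``eta = kappa**2 / 4``; ``kappa <= 0`` is monostable.
    delta : float
        Linear diffusion coefficient (seed dispersion scale), > 0.
    gamma_nl : float
        Coefficient of the biomass-dependent (nonlinear) Laplacian term,
        >= 0.  This is the term that can destabilise a uniform cover.
    alpha_nl : float
        Coefficient of the biomass-dependent biharmonic term, > 0.  It
        provides the short-scale cut-off selecting a finite wavelength.
    """

    eta: float
    kappa: float
    delta: float
    gamma_nl: float
    alpha_nl: float

    def __post_init__(self) -> None:
        for name in ("eta", "kappa", "delta", "gamma_nl", "alpha_nl"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.alpha_nl <= 0:
            raise ValueError(f"alpha_nl must be > 0, got {self.alpha_nl}")
        if self.gamma_nl < 0:
            raise ValueError(f"gamma_nl must be >= 0, got {self.gamma_nl}")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class SteadyStateSet:
    """Homogeneous steady states of the kinetics at fixed parameters.

    ``bare`` is always 0.  The vegetated branches
    ``rho_plus >= rho_minus`` exist only for ``kappa > 0`` and
    ``eta <= kappa**2/4``; at the fold they coalesce at
    ``rho = kappa/2``.  ``limit_point`` is the fold ``(rho_L, eta_L)``
    (present whenever ``kappa > 0``).
    """

    bare: float
    vegetated_upper: Optional[float]
    vegetated_lower: Optional[float]
    limit_point: Optional[tuple[float, float]]

    @property
    def states(self) -> list[float]:
        """All distinct steady states, ascending."""
        out = [self.bare]
        for s in (self.vegetated_lower, self.vegetated_upper):
            if s is not None and all(abs(s - o) > 0 for o in out):
                out.append(s)
        return sorted(out)


@dataclasses.dataclass(frozen=True)
class DispersionResult:
    """Outcome of the linear stability analysis about a uniform state."""

    rho_s: float
    critical_wavenumber: Optional[float]
    wavelength: Optional[float]


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if not np.isfinite(rho).all():
        raise ValueError("rho must be finite")
    return rho


def kinetics(rho, params: ModelParams):
    """Local reaction term f(rho) = -rho (eta - kappa rho + rho^2).

    Zero at the bare state and at both vegetated branches; positive
    between the lower and upper vegetated states (net growth), negative
    elsewhere (net decay).  Accepts scalars or arrays.
    """
    rho = _check_rho(rho)
    out = -rho * (params.eta - params.kappa * rho + rho * rho)
    return float(out) if out.ndim == 0 else out


def kinetics_derivative(rho, params: ModelParams):
    """df/drho, the local growth rate of perturbations about ``rho``."""
    rho = _check_rho(rho)
    out = -(params.eta - 2.0 * params.kappa * rho + 3.0 * rho * rho)
    return float(out) if out.ndim == 0 else out


def homogeneous_states(params: ModelParams) -> SteadyStateSet:
    """Solve f(rho)=0 for the uniform states at the given parameters.

    The vegetated roots solve ``eta - kappa*rho + rho^2 = 0``:
    ``rho_s± = (kappa ± sqrt(kappa^2 - 4 eta)) / 2``.  They are real and
    positive only for ``kappa > 0`` with ``eta <= kappa^2/4``.
    """
    lp = (params.kappa / 2.0, params.kappa**2 / 4.0) if params.kappa > 0 else None
    disc = params.kappa**2 - 4.0 * params.eta
    if params.kappa <= 0 or disc < 0:
        return SteadyStateSet(0.0, None, None, lp)
    root = math.sqrt(disc)
    lower = (params.kappa - root) / 2.0
    upper = (params.kappa + root) / 2.0
    return SteadyStateSet(0.0, upper, lower, lp)


def limit_point(params: ModelParams) -> tuple[float, float]:
    """Fold of the vegetated branches: (rho_L, eta_L) = (kappa/2, kappa^2/4).

    Raises
    ------
    ValueError
        If ``kappa <= 0`` (no vegetated branch, hence no fold).
    """
    if params.kappa <= 0:
        raise ValueError("no limit point: kappa must be > 0")
    return params.kappa / 2.0, params.kappa**2 / 4.0


def _require_steady(rho_s: float, params: ModelParams, tol: float) -> None:
    f = kinetics(rho_s, params)
    scale = max(1.0, abs(rho_s))
    if abs(f) > tol * scale:
        raise ValueError(
            f"rho_s={rho_s} is not a steady state (|f|={abs(f):.3g} > {tol:.1g})"
        )


def dispersion_relation(k, rho_s: float, params: ModelParams, *, check: bool = True):
    """Growth rate sigma(k) of a Fourier mode about the uniform state.

    Linearising the equation about ``rho_s`` gives

        sigma(k) = f'(rho_s) - (delta - gamma_nl*rho_s) k^2
                   - alpha_nl*rho_s k^4 .

    ``sigma`` is even in ``k`` and, for any vegetated state, tends to
    -inf as ``k -> inf`` (the biharmonic cut-off).  For the bare state
    it reduces to ``-eta - delta k^2``: bare soil is linearly stable.

    Parameters
    ----------
    k : array_like
        Angular wavenumber(s).
    rho_s : float
        A homogeneous steady state (validated unless ``check=False``).
    """
    if check:
        _require_steady(rho_s, params, STEADY_STATE_TOL)
    k = np.asarray(k, dtype=float)
    k2 = k * k
    out = (
        kinetics_derivative(rho_s, params)
        - (params.delta - params.gamma_nl * rho_s) * k2
        - params.alpha_nl * rho_s * k2 * k2
    )
    return float(out) if out.ndim == 0 else out


def critical_wavenumber(rho_s: float, params: ModelParams, *, check: bool = True) -> DispersionResult:
    """Wavenumber maximising sigma(k) about a vegetated state, if any.

    A finite-wavelength maximum exists only when the destabilising
    nonlinear diffusion overcomes the linear one, ``gamma_nl*rho_s >
    delta``; then

        k_c = sqrt((gamma_nl*rho_s - delta) / (2 alpha_nl rho_s)),

    the stationary point of sigma, and the intrinsic wavelength is
    ``Lambda = 2 pi / k_c``.  Otherwise sigma decreases monotonically in
    ``|k|`` and the result carries no wavenumber.
    """
    if rho_s <= 0:
        raise ValueError("critical_wavenumber requires a vegetated state rho_s > 0")
    if check:
        _require_steady(rho_s, params, STEADY_STATE_TOL)
    num = params.gamma_nl * rho_s - params.delta
    if num <= 0:
        return DispersionResult(rho_s, None, None)
    kc = math.sqrt(num / (2.0 * params.alpha_nl * rho_s))
    return DispersionResult(rho_s, kc, 2.0 * math.pi / kc)


def turing_threshold(
    kappa: float,
    delta: float,
    gamma_nl: float,
    alpha_nl: float,
) -> list[tuple[float, float]]:
    """Finite-wavenumber instability thresholds along the vegetated branch.

    On the branch ``eta = kappa*rho_s - rho_s^2`` the marginality
    condition ``max_k sigma(k) = 0`` reduces, after eliminating ``eta``,
    to a cubic in ``rho_s``:

        4 alpha_nl rho^2 (kappa - 2 rho) + (gamma_nl rho - delta)^2 = 0.

    Every real root in ``(0, kappa)`` for which a finite critical
    wavenumber exists is returned as ``(rho_c, eta_c)`` with
    ``eta_c = kappa*rho_c - rho_c^2``, sorted ascending in ``rho_c``.
    There may be more than one threshold; none is silently preferred.
    An empty list means the branch has no marginal point (e.g.
    ``gamma_nl = 0`` with ``delta > 0``).
    """
    if kappa <= 0:
        raise ValueError("turing_threshold requires kappa > 0")
    # cubic coefficients: -8a r^3 + (4ak + g^2) r^2 - 2gd r + d^2 = 0
    coeffs = [
        -8.0 * alpha_nl,
        4.0 * alpha_nl * kappa + gamma_nl**2,
        -2.0 * gamma_nl * delta,
        delta**2,
    ]
    roots = np.roots(coeffs)
    out: list[tuple[float, float]] = []
    for r in roots:
        if abs(r.imag) > 1e-10:
            continue
        rho_c = float(r.real)
        if not (0.0 < rho_c < kappa):
            continue
        if gamma_nl * rho_c <= delta:
            continue  # no finite-wavelength maximum at this density
        eta_c = kappa * rho_c - rho_c**2
        if eta_c <= 0:
            continue
        p = ModelParams(eta=eta_c, kappa=kappa, delta=delta,
                        gamma_nl=gamma_nl, alpha_nl=alpha_nl)
        disp = critical_wavenumber(rho_c, p, check=False)
        sigma_max = dispersion_relation(disp.critical_wavenumber, rho_c, p, check=False)
        if abs(sigma_max) < 1e-8:
            out.append((rho_c, eta_c))
    return sorted(out)


def bifurcation_diagram(
    eta_values,
    kappa: float,
    delta: float,
    gamma_nl: float,
    alpha_nl: float,
):
    """Tabulate the uniform branches and their stability along eta.

    Returns a :class:`pandas.DataFrame` with columns ``eta``,
    ``rho_bare``, ``rho_minus``, ``rho_plus``, ``bare_stable``,
    ``minus_stable``, ``plus_uniform_stable`` and ``plus_turing_unstable``
    (True where the upper branch has a band of growing wavenumbers).
    """
    import pandas as pd

    rows = []
    for eta in np.asarray(eta_values, dtype=float):
        p = ModelParams(eta=eta, kappa=kappa, delta=delta,
                        gamma_nl=gamma_nl, alpha_nl=alpha_nl)
        ss = homogeneous_states(p)
        row = {
            "eta": eta,
            "rho_bare": 0.0,
            "rho_minus": np.nan,
            "rho_plus": np.nan,
            "bare_stable": eta > 0,
            "minus_stable": False,
            "plus_uniform_stable": False,
            "plus_turing_unstable": False,
        }
        if ss.vegetated_upper is not None:
            row["rho_minus"] = ss.vegetated_lower
            row["rho_plus"] = ss.vegetated_upper
            row["minus_stable"] = kinetics_derivative(ss.vegetated_lower, p) < 0
            row["plus_uniform_stable"] = kinetics_derivative(ss.vegetated_upper, p) < 0
            disp = critical_wavenumber(ss.vegetated_upper, p, check=False)
            if disp.critical_wavenumber is not None:
                row["plus_turing_unstable"] = (
                    dispersion_relation(disp.critical_wavenumber, ss.vegetated_upper,
                                        p, check=False) > 0
                )
        rows.append(row)
    return pd.DataFrame(rows)
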
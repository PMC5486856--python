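"""Pure pointwise functions of the wound-contraction model.

All functions are form-invariant under the non-dimensionalisation in
:mod:`burncontract.parameters`: they accept either the dimensional
parameter collection or the starred (dimensionless) one, together with
state values in the matching units.  Arguments broadcast as numpy arrays.

Conventions
-----------
* The total (myo)fibroblast density is ``F = N + M``.
* ``grad_u`` is the *Eulerian* displacement gradient ``du_i/dx_j``; the
  left Cauchy-Green tensor is ``B = (I - grad_u - grad_u^T +
  grad_u^T grad_u)^{-1}``, i.e. stresses are evaluated on the deformed
  configuration.
* Plane strain: the out-of-plane stretch is 1, so ``B_zz = 1`` and the
  trace/determinant entering the constitutive law are the 3D ones.
* The saturation constant of the traction potential is called
  ``R_rho_const`` to keep it apart from the collagen reaction term.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "wound_indicator",
    "initial_state",
    "mmp_level",
    "reactions",
    "fluxes",
    "cauchy_stress",
    "body_force_potential",
    "robin_traction",
]


def wound_indicator(X, c_I: float, c_II: float):
    """Smooth indicator of intact dermis: 0 in the wound, 1 outside.

    ``X`` is a point or array of points (last axis = 2) in cm; the value
    ramps sinusoidally from 0 to 1 across the annulus
    ``| ||X|| - c_I | <= c_II``.
    """
    if not (c_I > c_II > 0.0):
        raise ValueError("wound geometry requires c_I > c_II > 0")
    X = np.asarray(X, dtype=float)
    r = np.linalg.norm(X, axis=-1) if X.shape[-1:] == (2,) else np.abs(X)
    return _indicator_of_radius(r, c_I, c_II)


def _indicator_of_radius(r, c_I: float, c_II: float):
    r = np.asarray(r, dtype=float)
    ramp = 0.5 * (1.0 + np.sin((r - c_I) * np.pi / (2.0 * c_II)))
    w = np.where(r < c_I - c_II, 0.0, np.where(r > c_I + c_II, 1.0, ramp))
    return w if w.ndim else float(w)


def initial_state(X, p, radius=None):
    """Initial fields (N, M, c, rho) at position(s) X.

    ``radius`` may be given instead of coordinates for radially symmetric
    setups.  N and rho start at the fraction ``I_w`` of their equilibrium
    values inside the wound, M at ``M_bar`` (zero) and the signal at
    ``c_w`` inside the wound, all blended by the wound indicator.
    """
    if radius is not None:
        w = _indicator_of_radius(radius, p.c_I, p.c_II)
    else:
        w = wound_indicator(X, p.c_I, p.c_II)
    fill = p.I_w + (1.0 - p.I_w) * w
    N = fill * p.N_bar
    M = np.broadcast_to(np.asarray(p.M_bar, dtype=float), np.shape(w)).copy() \
        if np.ndim(w) else p.M_bar
    c = (1.0 - w) * p.c_w
    rho = fill * p.rho_bar
    return N, M, c, rho


def mmp_level(F, c, rho, a_c_III: float):
    """Generic MMP concentration ``g = F rho / (1 + a_c_III c)``.

    Linear in cells and collagen, inhibited by the signaling molecule.
    """
    return np.asarray(F) * np.asarray(rho) / (1.0 + a_c_III * np.asarray(c))


def _growth_factor(F, kappa_F):
    """Logistic crowding factor, clamped at zero for very dense tissue."""
    raw = 1.0 - kappa_F * np.asarray(F)
    if np.any(raw < 0.0):
        warnings.warn("crowding factor 1 - kappa_F F went negative; clamped "
                      "to 0", RuntimeWarning, stacklevel=3)
    return np.maximum(raw, 0.0)


def reactions(N, M, c, rho, p, q: float, delta_rho: float):
    """Reaction kinetics (R_N, R_M, R_c, R_rho).

    * fibroblasts: adjusted logistic growth (exponent ``1 + q``),
      signal-enhanced, minus differentiation and apoptosis;
    * myofibroblasts: signal-gated logistic growth plus differentiation
      influx, minus apoptosis;
    * signal: saturating net secretion by F = N + eta M minus MMP
      proteolysis;
    * collagen: secretion with signal enhancement minus MMP proteolysis.

    The fractional power ``z**(1+q)`` has ``1 + q > 0`` for the defaults,
    so it evaluates to 0 at z = 0.  Negative state values are a domain
    error.
    """
    N, M, c, rho = (np.asarray(a, dtype=float) for a in (N, M, c, rho))
    if np.any(N < 0) or np.any(M < 0) or np.any(c < 0) or np.any(rho < 0):
        raise ValueError("reactions: negative state component "
                         "(fractional powers undefined)")
    F = N + M
    crowd = _growth_factor(F, p.kappa_F)
    hill_I = c / (p.a_c_I + c)
    g = mmp_level(F, c, rho, p.a_c_III)
    R_N = (p.r_F * (1.0 + p.r_F_max * hill_I) * crowd * N ** (1.0 + q)
           - p.k_F * c * N - p.delta_N * N)
    R_M = (p.r_F * ((1.0 + p.r_F_max) * hill_I) * crowd * M ** (1.0 + q)
           + p.k_F * c * N - p.delta_M * M)
    R_c = (p.k_c * (c / (p.a_c_II + c)) * (N + p.eta * M) - p.delta_c * g * c)
    R_rho = (p.k_rho * (1.0 + p.k_rho_max * c / (p.a_c_IV + c))
             * (N + p.eta * M) - delta_rho * g * rho)
    return R_N, R_M, R_c, R_rho


def fluxes(N, M, c, grad_N, grad_M, grad_c, p):
    """Constituent fluxes (J_N, J_M, J_c, J_rho).

    Cells: density-dependent Fickian diffusion ``-D_F F grad`` plus
    chemotaxis ``chi_F z grad c`` (up the signal gradient).  Signal:
    linear Fickian diffusion.  Collagen: no transport, J_rho = 0.
    """
    N, M = np.asarray(N, dtype=float), np.asarray(M, dtype=float)
    grad_N = np.asarray(grad_N, dtype=float)
    grad_M = np.asarray(grad_M, dtype=float)
    grad_c = np.asarray(grad_c, dtype=float)
    F = N + M
    J_N = -p.D_F * _colvec(F, grad_N) * grad_N \
        + p.chi_F * _colvec(N, grad_c) * grad_c
    J_M = -p.D_F * _colvec(F, grad_M) * grad_M \
        + p.chi_F * _colvec(M, grad_c) * grad_c
    J_c = -p.D_c * grad_c
    J_rho = np.zeros_like(grad_c)
    return J_N, J_M, J_c, J_rho


def _colvec(z, grad):
    z = np.asarray(z, dtype=float)
    return z[..., None] if np.ndim(grad) > z.ndim else z


class MechanicsFailure(RuntimeError):
    """Singular/inverted deformation; the caller should cut the time step."""


def left_cauchy_green(grad_u):
    """Plane-strain left Cauchy-Green tensor from the Eulerian grad u.

    Returns ``(B2, B_zz)`` where B2 is the in-plane 2x2 block and
    ``B_zz = 1``.  Raises :class:`MechanicsFailure` on a singular
    deformation.
    """
    grad_u = np.asarray(grad_u, dtype=float)
    I2 = np.eye(2)
    A = I2 - grad_u - np.swapaxes(grad_u, -1, -2) + \
        np.swapaxes(grad_u, -1, -2) @ grad_u
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    if np.any(det <= 0.0) or np.any(~np.isfinite(det)):
        raise MechanicsFailure("singular or inverted deformation")
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1]
    inv[..., 1, 1] = A[..., 0, 0]
    inv[..., 0, 1] = -A[..., 0, 1]
    inv[..., 1, 0] = -A[..., 1, 0]
    B2 = inv / det[..., None, None]
    return B2, np.ones_like(det)


def neo_hookean_stress_principal(lam_r, lam_t, rho, p):
    """Cauchy stress for a diagonal plane-strain deformation.

    ``lam_r``/``lam_t`` are the in-plane principal stretches (out-of-plane
    stretch 1).  Returns (sigma_rr, sigma_tt, sigma_zz).  Used by the
    axisymmetric solver; algebraically the principal-axis special case of
    :func:`cauchy_stress`.
    """
    lam_r = np.asarray(lam_r, dtype=float)
    lam_t = np.asarray(lam_t, dtype=float)
    rho = np.asarray(rho, dtype=float)
    J = lam_r * lam_t                     # sqrt(det B)
    if np.any(J <= 0.0):
        raise MechanicsFailure("non-positive areal Jacobian")
    C1 = p.E * rho / (4.0 * (1.0 + p.nu))
    D1 = p.E * rho / (6.0 * (1.0 - 2.0 * p.nu))
    trB = lam_r ** 2 + lam_t ** 2 + 1.0
    pref = 2.0 * C1 * J ** (-5.0 / 3.0)
    vol = 2.0 * D1 * (J - 1.0)
    s_rr = pref * (lam_r ** 2 - trB / 3.0) + vol
    s_tt = pref * (lam_t ** 2 - trB / 3.0) + vol
    s_zz = pref * (1.0 - trB / 3.0) + vol
    return s_rr, s_tt, s_zz


def cauchy_stress(grad_u, rho, p):
    """Plane-strain compressible neo-Hookean Cauchy stress.

    ``sigma = 2 C1 det(B)^{-5/6} (B - tr(B)/3 I) + 2 D1 (sqrt(det B) - 1) I``
    with ``C1 = E rho / (4 (1 + nu))``, ``D1 = E rho / (6 (1 - 2 nu))`` —
    a neo-Hookean solid whose Young's modulus ``E rho`` tracks the local
    collagen concentration.  Returns ``(sigma2, sigma_zz)``: in-plane 2x2
    block (symmetric) and out-of-plane normal stress.
    """
    grad_u = np.asarray(grad_u, dtype=float)
    rho = np.asarray(rho, dtype=float)
    B2, _ = left_cauchy_green(grad_u)
    detB = B2[..., 0, 0] * B2[..., 1, 1] - B2[..., 0, 1] * B2[..., 1, 0]
    trB = B2[..., 0, 0] + B2[..., 1, 1] + 1.0
    J = np.sqrt(detB)
    C1 = p.E * rho / (4.0 * (1.0 + p.nu))
    D1 = p.E * rho / (6.0 * (1.0 - 2.0 * p.nu))
    pref = (2.0 * C1 * J ** (-5.0 / 3.0))[..., None, None]
    I2 = np.eye(2)
    dev2 = B2 - (trB / 3.0)[..., None, None] * I2
    vol = (2.0 * D1 * (J - 1.0))[..., None, None]
    sigma2 = pref * dev2 + vol * I2
    sigma_zz = (2.0 * C1 * J ** (-5.0 / 3.0)) * (1.0 - trB / 3.0) \
        + 2.0 * D1 * (J - 1.0)
    return sigma2, sigma_zz


def body_force_potential(M, rho, p):
    """Myofibroblast traction potential ``psi = xi M rho/(R^2 + rho^2)``.

    The body force entering the balance is ``f = div(psi I) = grad psi``;
    solvers add ``psi`` isotropically to the stress in their weak forms.
    ``psi`` is non-negative, vanishes with M, and is maximal in rho at
    ``rho = R_rho_const``.
    """
    M = np.asarray(M, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return p.xi * M * rho / (p.R_rho_const ** 2 + rho ** 2)


def robin_traction(u, rho, n, s_const: float):
    """Spring-like boundary traction ``n . sigma = -s rho u`` (N/cm^2)."""
    u = np.asarray(u, dtype=float)
    return -s_const * np.asarray(rho, dtype=float) * u
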
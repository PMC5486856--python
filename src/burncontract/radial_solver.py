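"""Axisymmetric (1D radial) engine for the burn-contraction model.

For circular burns the full plane-strain problem reduces to a radial one
on a disk.  This engine is the workhorse for the 144-run factorial and
the 100-draw Monte-Carlo experiments; the 2D FEM
(:mod:`burncontract.fem2d`) validates it on matched geometry.

Scheme (method of lines, all quantities non-dimensionalised):

* Lagrangian moving grid — nodes convect with the material velocity, so
  the advective term reduces exactly to the dilution captured by the
  changing finite-volume cell sizes.
* Backward Euler in time with a fixed-point defect correction between
  the constituent block and the mechanics block (at most 5 sweeps, then
  the step is restarted at 85% of its size).
* Constituents: conservative finite volumes on the deformed grid;
  density-dependent diffusion with interface-averaged coefficients;
  chemotaxis upwinded at cell interfaces; Patankar source splitting
  (production explicit in the sweep iterate, sinks implicit) — together
  these keep all four fields non-negative at every accepted step.
* Mechanics: the compressible neo-Hookean balance becomes a two-point
  boundary value problem in the radial displacement, solved by damped
  Newton with an analytic residual and a colored finite-difference
  tridiagonal Jacobian; the spring boundary condition closes the outer
  edge, symmetry (u = 0) the center.
* Adaptive time steps with local-truncation-error control against a
  second-order variable-step predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from . import model_equations as me
from . import observables as obs
from . import parameters as par

__all__ = [
    "RadialMesh",
    "RadialState",
    "TimeStepController",
    "StepFailureError",
    "build_radial_mesh",
    "build_radial_problem",
    "advance_one_step",
    "adapt_dt",
    "run_simulation",
]

_DT_UNDERFLOW = 1e-12


class StepFailureError(RuntimeError):
    """Time step shrank below the underflow limit; carries diagnostics."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class RadialMesh:
    """Graded node radii r_0 = 0 < ... < r_K = R_domain (cm)."""

    radii: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "radii", r)
        if r[0] != 0.0:
            raise ValueError("radial mesh must start at r = 0")
        h = np.diff(r)
        if np.any(h <= 0.0):
            raise ValueError("node radii must be strictly increasing")
        ratio = np.maximum(h[1:] / h[:-1], h[:-1] / h[1:])
        if ratio.size and ratio.max() > 1.3 + 1e-9:
            raise ValueError("grading ratio between adjacent cells exceeds 1.3")

    @property
    def n_nodes(self) -> int:
        return len(self.radii)


@dataclass
class TimeStepController:
    """Adaptive time-step state and rules (dimensionless units)."""

    dt: float = 1e-5
    dt_init_max: float = 1e-5
    dt_max: float = 1e-3
    growth_max: float = 1.25
    shrink_min: float = 0.25
    nonconv_factor: float = 0.85
    abs_tol: float = 1e-2
    rel_tol: float = 5e-2
    safety: float = 0.9


@dataclass
class RadialState:
    """Solution snapshot on the material grid.

    ``z`` stacks the dimensionless fields (n, m, c, rho) per node; ``u``
    is the total radial displacement of each material node and ``v`` the
    material velocity of the last accepted step.  ``z_prev``/``dt_prev``
    carry one step of history for the truncation-error estimate.
    """

    t: float
    z: np.ndarray
    u: np.ndarray
    v: np.ndarray
    z_prev: np.ndarray | None = None
    dt_prev: float | None = None


@dataclass
class RadialProblem:
    p_dim: par.DimensionalParameters
    p: par.DimensionalParameters          # dimensionless collection
    q: float
    delta_rho: float                      # dimensionless
    scales: par.ScalingSet
    mesh: RadialMesh
    diag: dict = field(default_factory=dict)

    def initial_state(self) -> RadialState:
        R = self.mesh.radii
        n, m, c, rho = me.initial_state(None, self.p, radius=R)
        z = np.vstack([n, np.broadcast_to(m, R.shape), c, rho]).astype(float)
        return RadialState(t=0.0, z=z, u=np.zeros_like(R),
                           v=np.zeros_like(R))


def _graded_segment(start: float, stop: float, h0: float, h_max: float,
                    ratio: float) -> np.ndarray:
    """Cell widths from `start` to `stop` growing geometrically from h0."""
    span = abs(stop - start)
    widths = []
    h = h0
    total = 0.0
    while total < span:
        widths.append(h)
        total += h
        h = min(h * ratio, h_max)
    w = np.array(widths)
    w *= span / w.sum()        # rescale to land exactly; preserves ratios
    return w


def build_radial_mesh(c_I: float, c_II: float, R_domain: float = 12.0,
                      h_min: float = 0.03, h_max: float = 0.4,
                      ratio: float = 1.25) -> RadialMesh:
    """Graded mesh, finest across the wound-edge annulus.

    The band [c_I - 2 c_II, c_I + 2 c_II] (where the initial profiles
    ramp) gets uniform width ``h_min``; cells grow geometrically by
    ``ratio`` (<= 1.3) away from it, capped at ``h_max``.
    """
    a = max(c_I - 2.0 * c_II, 0.0)
    b = min(c_I + 2.0 * c_II, R_domain)
    n_band = max(int(np.ceil((b - a) / h_min)), 2)
    band = np.linspace(a, b, n_band + 1)
    inner = a - np.cumsum(_graded_segment(a, 0.0, h_min, h_max, ratio))[::-1]
    inner[0] = 0.0 if inner.size else inner
    outer = b + np.cumsum(_graded_segment(b, R_domain, h_min, h_max, ratio))
    if outer.size:
        outer[-1] = R_domain
    radii = np.concatenate([inner, band, outer])
    return RadialMesh(radii=radii)


def build_radial_problem(p: par.DimensionalParameters,
                         R_domain: float = 12.0,
                         h_min: float = 0.03,
                         h_max: float = 0.4) -> RadialProblem:
    """Discretise the model on a disk of radius ``R_domain`` (cm)."""
    if R_domain < p.c_I + 2.0 * p.c_II:
        raise ValueError("R_domain must contain the wound and its edge ramp")
    rep = par.validate(p)
    if not rep.ok:
        raise ValueError("invalid parameters: " + "; ".join(rep.violations))
    d = par.derive_consistent_constants(p)
    if p.c_w == 0.0:
        # no initial signal anywhere: c = 0 is invariant, so any positive
        # concentration scale works; borrow a_c_I and keep c*(0) = 0
        p_scaled = par.with_overrides(p, c_w=p.a_c_I)
        p_star, d_star, scales = par.nondimensionalise(
            p_scaled, par.derive_consistent_constants(p_scaled))
        p_star.c_w = 0.0
    else:
        p_star, d_star, scales = par.nondimensionalise(p, d)
    mesh = build_radial_mesh(p_star.c_I, p_star.c_II,
                             R_domain / scales.length_scale, h_min, h_max)
    return RadialProblem(p_dim=p, p=p_star, q=d_star.q,
                         delta_rho=d_star.delta_rho, scales=scales, mesh=mesh)


# ---------------------------------------------------------------------------
# constituent block: finite volumes on the moving grid


def _volumes(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dual-cell volumes (per radian) and interface radii."""
    r_face = 0.5 * (r[:-1] + r[1:])
    left = np.concatenate([[r[0]], r_face])
    right = np.concatenate([r_face, [r[-1]]])
    V = 0.5 * (right ** 2 - left ** 2)
    return V, r_face


def _tridiag_solve(lower, diag, upper, rhs):
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs)


def _transport_solve(z_old, V_old, V_new, r_new, r_face, dt, diff_face,
                     vel_face, sink, prod, dirichlet):
    """One implicit FV solve: (V/dt + sinks + transport) z = V_old z_old/dt + prod.

    ``diff_face``/``vel_face`` are diffusion coefficients and advective
    velocities at interfaces (upwinded), ``sink``/``prod`` the Patankar
    split reaction pieces per node, ``dirichlet`` an optional outer value.
    """
    K = len(z_old)
    dr = np.diff(r_new)
    g = r_face * diff_face / dr
    wp = np.maximum(vel_face, 0.0) * r_face
    wm = np.maximum(-vel_face, 0.0) * r_face
    diag = V_new / dt + sink * V_new
    lower = np.zeros(K - 1)
    upper = np.zeros(K - 1)
    diag[:-1] += g + wp
    diag[1:] += g + wm
    upper -= g + wm
    lower -= g + wp
    rhs = V_old * z_old / dt + prod * V_new
    if dirichlet is not None:
        diag[-1] = 1.0
        lower[-1] = 0.0
        rhs[-1] = dirichlet
    return _tridiag_solve(lower, diag, upper, rhs)


def _constituent_sweep(prob, z_old, V_old, z_it, r_new, dt):
    """Gauss-Seidel sweep over (n, m, c, rho) with Patankar splitting."""
    p, q = prob.p, prob.q
    V_new, r_face = _volumes(r_new)
    n_it, m_it, c_it, rho_it = z_it
    F_it = n_it + m_it
    crowd = np.maximum(1.0 - p.kappa_F * F_it, 0.0)
    hill_I = c_it / (p.a_c_I + c_it)
    dr = np.diff(r_new)

    F_face = 0.5 * (F_it[:-1] + F_it[1:])
    grad_c = (c_it[1:] - c_it[:-1]) / dr
    chemo = p.chi_F * grad_c

    # fibroblasts
    prod_n = p.r_F * (1.0 + p.r_F_max * hill_I) * crowd * n_it ** (1.0 + q)
    sink_n = p.k_F * c_it + p.delta_N
    n_new = _transport_solve(z_old[0], V_old, V_new, r_new, r_face, dt,
                             p.D_F * F_face, chemo, sink_n, prod_n,
                             dirichlet=p.N_bar)
    # myofibroblasts
    prod_m = (p.r_F * ((1.0 + p.r_F_max) * hill_I) * crowd
              * m_it ** (1.0 + q) + p.k_F * c_it * n_new)
    sink_m = np.full_like(m_it, p.delta_M)
    m_new = _transport_solve(z_old[1], V_old, V_new, r_new, r_face, dt,
                             p.D_F * F_face, chemo, sink_m, prod_m,
                             dirichlet=p.M_bar)
    F_new = n_new + m_new
    # signaling molecule
    prod_c = p.k_c * (c_it / (p.a_c_II + c_it)) * (n_new + p.eta * m_new)
    sink_c = p.delta_c * F_new * rho_it / (1.0 + p.a_c_III * c_it)
    c_new = _transport_solve(z_old[2], V_old, V_new, r_new, r_face, dt,
                             np.full_like(dr, p.D_c), np.zeros_like(dr),
                             sink_c, prod_c, dirichlet=0.0)
    # collagen: no transport; pointwise Patankar update with dilution
    prod_rho = (p.k_rho * (1.0 + p.k_rho_max * c_new / (p.a_c_IV + c_new))
                * (n_new + p.eta * m_new))
    sink_rho = prob.delta_rho * F_new * rho_it / (1.0 + p.a_c_III * c_new)
    rho_new = ((V_old * z_old[3] / dt + prod_rho * V_new)
               / (V_new / dt + sink_rho * V_new))
    return np.vstack([n_new, m_new, c_new, rho_new])


def _residual_norms(prob, z_old, V_old, z_it, r_new, dt):
    """Relative 1-norms of the implicit-system residuals at the iterate."""
    p, q = prob.p, prob.q
    V_new, r_face = _volumes(r_new)
    n, m, c, rho = z_it
    R_N, R_M, R_c, R_rho = me.reactions(n, m, c, rho, p, q, prob.delta_rho)
    dr = np.diff(r_new)
    out = []
    F_face = 0.5 * ((n + m)[:-1] + (n + m)[1:])
    for k, (z, R, dcoef, chemo_z) in enumerate((
            (n, R_N, p.D_F * F_face, n), (m, R_M, p.D_F * F_face, m),
            (c, R_c, np.full_like(dr, p.D_c), None), (rho, R_rho, None, None))):
        flux = np.zeros_like(z)
        if dcoef is not None:
            dflux = r_face * dcoef * (z[1:] - z[:-1]) / dr
            if chemo_z is not None:
                w = p.chi_F * (c[1:] - c[:-1]) / dr
                up = np.where(w > 0, chemo_z[:-1], chemo_z[1:])
                dflux -= r_face * w * up
            flux[:-1] += dflux
            flux[1:] -= dflux
        res = (V_new * z - V_old * z_old[k]) / dt - flux - R * V_new
        rhs = np.abs(V_old * z_old[k]) / dt + np.abs(R) * V_new + np.abs(flux)
        if dcoef is not None:        # Dirichlet node excluded
            res = res[:-1]
            rhs = rhs[:-1]
        out.append(np.sum(np.abs(res)) / max(np.sum(rhs), 1e-300))
    return np.array(out)


# ---------------------------------------------------------------------------
# mechanics block: radial neo-Hookean two-point BVP


def _mech_residual(u, prob, rho, psi):
    """Weak-form residual of the radial force balance (interior nodes)."""
    p = prob.p
    R = prob.mesh.radii
    dR = np.diff(R)
    lam_r = 1.0 + np.diff(u) / dR
    Rm = 0.5 * (R[:-1] + R[1:])
    um = 0.5 * (u[:-1] + u[1:])
    lam_t = (Rm + um) / Rm
    rho_m = 0.5 * (rho[:-1] + rho[1:])
    psi_m = 0.5 * (psi[:-1] + psi[1:])
    s_rr, s_tt, _ = me.neo_hookean_stress_principal(lam_r, lam_t, rho_m, p)
    s_rr += psi_m
    s_tt += psi_m
    res = np.zeros_like(u)
    res[:-1] += -s_rr * lam_t * Rm + 0.5 * s_tt * lam_r * dR
    res[1:] += s_rr * lam_t * Rm + 0.5 * s_tt * lam_r * dR
    r_out = R[-1] + u[-1]
    res[-1] -= r_out * (-p.s * rho[-1] * u[-1] + psi[-1])
    return res[1:]                    # u[0] = 0 by symmetry


def _mech_jacobian(u, prob, rho, psi, res0):
    """Tridiagonal FD Jacobian via 3-coloring of the nodes."""
    n = len(u) - 1
    lower = np.zeros(n - 1)
    diag = np.zeros(n)
    upper = np.zeros(n - 1)
    h = 1e-7
    for color in range(3):
        up = u.copy()
        cols = np.arange(1 + color, len(u), 3)
        up[cols] += h
        dres = (_mech_residual(up, prob, rho, psi) - res0) / h
        for j in cols - 1:            # residual index of perturbed node
            diag[j] = dres[j]
            if j > 0:
                upper[j - 1] = dres[j - 1]
            if j < n - 1:
                lower[j] = dres[j + 1]
    return lower, diag, upper


def _solve_mechanics(prob, u_init, rho, psi, max_iter=30):
    """Damped Newton on the radial displacement; returns u with u[0]=0."""
    u = u_init.copy()
    u[0] = 0.0
    try:
        res = _mech_residual(u, prob, rho, psi)
    except me.MechanicsFailure:
        u = np.zeros_like(u)
        res = _mech_residual(u, prob, rho, psi)
    norm = np.max(np.abs(res))
    tol = 1e-11 + 1e-10 * norm
    for _ in range(max_iter):
        if norm <= tol:
            return u
        lower, diag, upper = _mech_jacobian(u, prob, rho, psi, res)
        try:
            du = _tridiag_solve(lower, diag, upper, res)
        except Exception as exc:       # singular Jacobian
            raise me.MechanicsFailure(str(exc)) from exc
        step = 1.0
        for _bt in range(10):
            u_try = u.copy()
            u_try[1:] -= step * du
            try:
                res_try = _mech_residual(u_try, prob, rho, psi)
            except me.MechanicsFailure:
                step *= 0.5
                continue
            norm_try = np.max(np.abs(res_try))
            if norm_try < norm or norm_try <= tol:
                u, res, norm = u_try, res_try, norm_try
                break
            step *= 0.5
        else:
            raise me.MechanicsFailure("mechanics line search stalled")
    raise me.MechanicsFailure("mechanics Newton did not converge")


def _body_potential(prob, m, rho):
    return me.body_force_potential(m, rho, prob.p)


# ---------------------------------------------------------------------------
# time stepping


def _attempt_step(prob, state: RadialState, dt: float):
    """One backward-Euler step with the fixed-point defect correction.

    Returns (z_new, u_new, n_sweeps) or None if the sweep limit is hit.
    """
    R = prob.mesh.radii
    V_old, _ = _volumes(R + state.u)
    z_it = state.z.copy()
    u_it = state.u.copy()
    for sweep in range(5):
        r_new = R + u_it
        z_new = _constituent_sweep(prob, state.z, V_old, z_it, r_new, dt)
        psi = _body_potential(prob, z_new[1], z_new[3])
        u_new = _solve_mechanics(prob, u_it, z_new[3], psi)
        diffs = []
        for k in range(4):
            num = np.sum(np.abs(z_new[k] - z_it[k]))
            den = max(np.sum(np.abs(z_new[k])), 1e-8 * len(R))
            diffs.append(num / den)
        du = np.sum(np.abs(u_new - u_it)) / max(np.sum(np.abs(u_new)), 1e-12)
        z_it, u_it = z_new, u_new
        # a first sweep solves constituents on the pre-step geometry, so the
        # dilution from mesh motion only enters from sweep two onward: never
        # exit before the fields have seen the updated volumes
        if sweep >= 1 and max(diffs) < 5e-2 and du < 5e-2:
            res = _residual_norms(prob, state.z, V_old, z_it, R + u_it, dt)
            if np.max(res) < 1.0:
                return z_it, u_it, sweep + 1
    return None


def adapt_dt(ctrl: TimeStepController, dt: float, error_ratio: float
             ) -> tuple[float, bool]:
    """Accept/reject a step from the normalized truncation-error ratio.

    ``error_ratio`` is max over nodes/fields of
    |error| / (abs_tol + rel_tol |z|); the step is accepted iff <= 1.
    Backward Euler has a second-order local error, so the target factor
    is ``safety / sqrt(error_ratio)``, clamped to the growth/shrink
    bounds and the dt cap.
    """
    accept = error_ratio <= 1.0
    if error_ratio > 0.0:
        factor = ctrl.safety / np.sqrt(error_ratio)
    else:
        factor = ctrl.growth_max
    factor = min(ctrl.growth_max, max(ctrl.shrink_min, factor))
    if not accept:
        factor = min(factor, 1.0)
    return min(dt * factor, ctrl.dt_max), accept


def advance_one_step(state: RadialState, ctrl: TimeStepController,
                     prob: RadialProblem) -> tuple[RadialState, dict]:
    """Advance by one *accepted* step; ``ctrl.dt`` is updated in place."""
    dt = ctrl.dt
    retries = 0
    while True:
        if dt < _DT_UNDERFLOW:
            raise StepFailureError(
                "time step underflow", {"t": state.t, "retries": retries})
        try:
            result = _attempt_step(prob, state, dt)
        except me.MechanicsFailure:
            result = None
        if result is None:            # fixed-point non-convergence
            dt *= ctrl.nonconv_factor
            retries += 1
            continue
        z_new, u_new, sweeps = result
        if state.z_prev is not None and state.dt_prev:
            pred = state.z + dt * (state.z - state.z_prev) / state.dt_prev
            lte = (z_new - pred) * dt / (2.0 * dt + state.dt_prev)
            ratio = float(np.max(
                np.abs(lte) / (ctrl.abs_tol + ctrl.rel_tol * np.abs(z_new))))
        else:
            lte = None
            ratio = 0.0
        dt_next, accept = adapt_dt(ctrl, dt, ratio)
        if accept:
            if np.min(z_new) < 0.0:
                raise StepFailureError(
                    "positivity violated", {"t": state.t, "min": z_new.min()})
            if lte is not None:
                # local extrapolation: subtracting the truncation-error
                # estimate lifts the accepted solution to second order;
                # clipped at zero to keep the positivity guarantee, and
                # mechanics re-solved so displacement stays consistent
                z_new = np.maximum(z_new - lte, 0.0)
                psi = _body_potential(prob, z_new[1], z_new[3])
                u_new = _solve_mechanics(prob, u_new, z_new[3], psi)
            new = RadialState(t=state.t + dt, z=z_new, u=u_new,
                              v=(u_new - state.u) / dt,
                              z_prev=state.z, dt_prev=dt)
            ctrl.dt = dt_next
            report = {"dt_used": dt, "dt_next": dt_next, "sweeps": sweeps,
                      "error_ratio": ratio, "retries": retries,
                      "accepted": True}
            return new, report
        dt = dt_next
        retries += 1


def run_simulation(p: par.DimensionalParameters,
                   t_end: float = 42.0,
                   output_times=None,
                   R_domain: float = 12.0,
                   h_min: float = 0.03,
                   dt_max: float | None = None,
                   n_boundary: int = 40) -> obs.SimulationResult:
    """Integrate from day 0 to ``t_end`` (days); record at ``output_times``.

    Deterministic given identical inputs.  Records the displaced
    40-point wound-boundary polygon and the 9-point Lagrangian probe
    averages of the myofibroblast density (cells/cm^3) and the collagen
    concentration (g/cm^3), both back in dimensional units.
    """
    if t_end > 310.0:
        raise ValueError("t_end beyond the supported healing window")
    prob = build_radial_problem(p, R_domain=R_domain, h_min=h_min)
    tau = prob.scales.time_scale
    if output_times is None:
        output_times = np.arange(0.0, t_end + 0.5, 1.0)
    output_times = np.asarray(sorted(output_times), dtype=float)
    if output_times[-1] > t_end + 1e-9:
        raise ValueError("output times beyond t_end")
    ctrl = TimeStepController()
    if dt_max is not None:
        ctrl.dt_max = dt_max
        ctrl.dt = min(ctrl.dt, dt_max)
    state = prob.initial_state()

    bpoints = obs.wound_boundary_points(prob.p.c_I, n_boundary)
    pprobes = obs.probe_points(prob.p.c_I)
    R = prob.mesh.radii

    polygons, probes_M, probes_rho, rec_times = [], [], [], []
    total_sweeps = total_steps = total_retries = 0

    def record(st: RadialState, t_day: float):
        u_b = np.interp(np.linalg.norm(bpoints, axis=1), R, st.u)
        scale_b = 1.0 + u_b / np.linalg.norm(bpoints, axis=1)
        polygons.append(bpoints * scale_b[:, None] * prob.scales.length_scale)
        r_probe = np.linalg.norm(pprobes, axis=1)
        m_vals = np.interp(r_probe, R, st.z[1])
        rho_vals = np.interp(r_probe, R, st.z[3])
        probes_M.append(m_vals.mean() * prob.scales.density_scale_cells)
        probes_rho.append(rho_vals.mean() * prob.scales.conc_scale_collagen)
        rec_times.append(t_day)

    out_star = output_times / tau
    next_out = 0
    if abs(out_star[0]) < 1e-12:
        record(state, output_times[0])
        next_out = 1
    t_end_star = t_end / tau
    while state.t < t_end_star - 1e-12:
        target = out_star[next_out] if next_out < len(out_star) else t_end_star
        saved_dt = ctrl.dt
        clamped = False
        if state.t + ctrl.dt > target:
            ctrl.dt = max(target - state.t, 1e-12)
            clamped = True
        state, rep = advance_one_step(state, ctrl, prob)
        if clamped and rep["retries"] == 0:
            # restoring the pre-clamp dt: output-time alignment is not an
            # accuracy rejection, so it must not throttle the step size
            ctrl.dt = min(saved_dt, ctrl.dt_max)
        total_steps += 1
        total_sweeps += rep["sweeps"]
        total_retries += rep["retries"]
        while next_out < len(out_star) and state.t >= out_star[next_out] - 1e-12:
            record(state, output_times[next_out])
            next_out += 1

    result = obs.SimulationResult(
        times=np.array(rec_times),
        boundary_polygons=np.array(polygons),
        probes={"M": np.array(probes_M), "rho": np.array(probes_rho)},
        engine="radial",
        diagnostics={"steps": total_steps, "sweeps": total_sweeps,
                     "retries": total_retries, "n_nodes": prob.mesh.n_nodes},
    )
    result.profiles["final_state"] = state
    result.profiles["problem"] = prob
    return result
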
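"""Model constants, derived constants, validation and non-dimensionalisation.

The model describes a circular burn on a patch of dermis with four
constituents — fibroblasts ``N`` (cells/cm^3), myofibroblasts ``M``
(cells/cm^3), a generic signaling molecule ``c`` (g/cm^3) and collagen
``rho`` (g/cm^3) — coupled to a quasi-static force balance for a
compressible neo-Hookean solid.  All constants are stored dimensionally
(units in the field docs below); solvers work on the non-dimensionalised
collection produced by :func:`nondimensionalise`.

Three constants are not free: the exponent ``q`` of the adjusted logistic
growth, the collagen degradation rate ``delta_rho`` and the far-field
signal level ``c_bar`` are forced by requiring that the homogeneous
unwounded state ``(N_bar, 0, 0, rho_bar)`` is a fixed point of the
kinetics.  :func:`derive_consistent_constants` computes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "DimensionalParameters",
    "DerivedParameters",
    "ScalingSet",
    "ValidationReport",
    "derive_consistent_constants",
    "nondimensionalise",
    "redimensionalise",
    "validate",
]


@dataclass
class DimensionalParameters:
    """All dimensional model constants.

    Defaults are the reference values; the four study factors default to
    the midpoints of their reported ranges (``delta_M`` = 3.5e-2 /day,
    ``k_rho`` = 2e-8 g/(cells day), ``I_w`` = 0.15, ``c_I`` = 3.78 cm).
    """

    D_F: float = 1e-7          # cm^5/(cells day), cell random motility
    chi_F: float = 2e-3        # cm^5/(g day), chemotactic coefficient
    r_F: float = 9.24e-1       # cm^{3q}/(cells^q day), cell division rate
    r_F_max: float = 2.0       # -, max division-rate enhancement
    a_c_I: float = 1e-8        # g/cm^3, half-max signal conc. for division
    kappa_F: float = 1e-6      # cm^3/cells, crowding coefficient
    k_F: float = 5.4e6         # cm^3/(g day), differentiation rate
    delta_N: float = 2e-2      # /day, fibroblast apoptosis rate
    delta_M: float = 3.5e-2    # /day, myofibroblast apoptosis rate (factor)
    D_c: float = 2.9e-3        # cm^2/day, signal diffusivity
    k_c: float = 4e-13         # g/(cells day), max net signal secretion
    eta: float = 2.0           # -, myo/fibro secretion ratio
    a_c_II: float = 1e-8       # g/cm^3, half-max signal conc. for secretion
    delta_c: float = 5e-4      # cm^6/(cells g day), signal breakdown rate
    a_c_III: float = 2e8       # cm^3/g, MMP-synthesis inhibition constant
    k_rho: float = 2e-8        # g/(cells day), collagen secretion rate (factor)
    k_rho_max: float = 10.0    # -, max secretion-rate enhancement
    a_c_IV: float = 1e-9       # g/cm^3, half-max signal conc. for secretion boost
    E: float = 1.0e2           # (N cm)/g, Young's modulus per unit collagen
    nu: float = 4.9e-1         # -, Poisson ratio
    xi: float = 5e-3           # (N g)/(cells cm^2), myofibroblast traction
    R_rho_const: float = 3e-1  # g/cm^3, traction saturation constant
    N_bar: float = 1e4         # cells/cm^3, equilibrium fibroblast density
    M_bar: float = 0.0         # cells/cm^3, equilibrium myofibroblast density
    rho_bar: float = 1e-1      # g/cm^3, equilibrium collagen concentration
    s: float = 1e3             # N/g, boundary spring constant
    I_w: float = 1.5e-1        # -, minimum initial wound fill (factor)
    c_w: float = 1e-8          # g/cm^3, initial wound signal concentration
    c_I: float = 3.78          # cm, initial wound radius (factor)
    c_II: float = 0.10         # cm, wound edge ramp half-width
    L: float = 1.0             # cm, length scale


@dataclass(frozen=True)
class DerivedParameters:
    """Consistency-forced constants (see :func:`derive_consistent_constants`)."""

    q: float            # -, adjusted-logistic exponent, negative
    delta_rho: float    # cm^6/(cells g day), collagen degradation rate
    c_bar: float        # g/cm^3, far-field signal concentration


@dataclass(frozen=True)
class ScalingSet:
    """Characteristic scales of the non-dimensionalisation.

    x = L x*, t = (L^2/(D_F N_bar)) t*, N = N_bar N*, M = N_bar M*,
    c = c_w c*, rho = rho_bar rho*, u = L u*, v = (D_F N_bar / L) v*,
    sigma = (xi N_bar / rho_bar) sigma*.
    """

    length_scale: float          # cm
    time_scale: float            # day per dimensionless time unit
    density_scale_cells: float   # cells/cm^3
    conc_scale_collagen: float   # g/cm^3
    conc_scale_signal: float     # g/cm^3
    velocity_scale: float        # cm/day
    stress_scale: float          # N/cm^2


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


class DegenerateParameterError(ValueError):
    """A parameter combination for which a derived constant is undefined."""


class ScalingError(ValueError):
    """A characteristic scale is undefined (e.g. c_w = 0)."""


_NONNEGATIVE = (
    "D_F", "chi_F", "r_F", "r_F_max", "a_c_I", "kappa_F", "k_F", "delta_N",
    "delta_M", "D_c", "k_c", "eta", "a_c_II", "delta_c", "a_c_III", "k_rho",
    "k_rho_max", "a_c_IV", "E", "xi", "R_rho_const", "N_bar", "M_bar",
    "rho_bar", "s", "I_w", "c_w", "L",
)


def validate(p: DimensionalParameters) -> ValidationReport:
    """Check every parameter invariant; returns pass/fail with named violations."""
    v: list[str] = []
    for name in _NONNEGATIVE:
        if getattr(p, name) < 0:
            v.append(f"{name}: negative rate/diffusivity/concentration")
    if not (0.0 < p.nu < 0.5):
        v.append("nu: must lie in (0, 0.5); at nu = 0.5 the incompressible "
                 "limit makes the volumetric modulus D1 = E rho/(6(1-2 nu)) "
                 "undefined")
    if 1.0 - p.kappa_F * p.N_bar <= 0.0:
        v.append("kappa_F * N_bar >= 1: crowding factor non-positive at the "
                 "unwounded equilibrium")
    if p.c_II <= 0.0:
        v.append("c_II: wound edge ramp width must be positive")
    if p.c_I <= p.c_II:
        v.append("c_I <= c_II: wound radius must exceed the edge ramp width")
    if p.N_bar <= 1.0:
        v.append("N_bar <= 1: log(N_bar) <= 0 makes the exponent q undefined")
    return ValidationReport(ok=not v, violations=v)


def derive_consistent_constants(p: DimensionalParameters) -> DerivedParameters:
    """Constants forced by stationarity of the unwounded state.

    With ``c_bar = 0`` the fibroblast kinetics vanish at ``N = N_bar`` iff

        q = [log(delta_N) - log(r_F (1 - kappa_F N_bar))] / log(N_bar)

    (any logarithm base; the ratio is base-invariant) and the collagen
    kinetics vanish at ``rho = rho_bar`` iff ``delta_rho = k_rho/rho_bar^2``.
    """
    if p.N_bar <= 1.0:
        raise DegenerateParameterError(
            "N_bar must exceed 1 (log(N_bar) > 0) for the exponent q")
    crowd = 1.0 - p.kappa_F * p.N_bar
    if crowd <= 0.0 or p.r_F <= 0.0 or p.delta_N <= 0.0:
        raise DegenerateParameterError(
            "q requires delta_N > 0, r_F > 0 and 1 - kappa_F N_bar > 0")
    q = (math.log(p.delta_N) - math.log(p.r_F * crowd)) / math.log(p.N_bar)
    delta_rho = p.k_rho / p.rho_bar ** 2
    return DerivedParameters(q=q, delta_rho=delta_rho, c_bar=0.0)


def nondimensionalise(
    p: DimensionalParameters, d: DerivedParameters | None = None
) -> tuple[DimensionalParameters, DerivedParameters, ScalingSet]:
    """Scale the model so the equations keep their dimensional form.

    Returns ``(p_star, d_star, scales)`` where ``p_star`` is a parameter
    collection of the same type whose values are the dimensionless groups:
    the equations evaluated with ``p_star`` on starred fields are the
    non-dimensionalised equations.  The starred collection has
    ``D_F = N_bar = rho_bar = c_w = xi = L = 1`` and the reaction-rate
    groups absorb the time scale ``L^2/(D_F N_bar)``.
    """
    if d is None:
        d = derive_consistent_constants(p)
    if p.c_w <= 0.0:
        raise ScalingError("c_w = 0: signal concentration scale undefined")
    if p.D_F <= 0.0 or p.N_bar <= 0.0 or p.rho_bar <= 0.0 or p.xi <= 0.0:
        raise ScalingError("D_F, N_bar, rho_bar, xi must be positive scales")
    tau = p.L ** 2 / (p.D_F * p.N_bar)          # day
    stress = p.xi * p.N_bar / p.rho_bar         # N/cm^2
    scales = ScalingSet(
        length_scale=p.L,
        time_scale=tau,
        density_scale_cells=p.N_bar,
        conc_scale_collagen=p.rho_bar,
        conc_scale_signal=p.c_w,
        velocity_scale=p.D_F * p.N_bar / p.L,
        stress_scale=stress,
    )
    p_star = DimensionalParameters(
        D_F=1.0,
        chi_F=p.chi_F * p.c_w / (p.D_F * p.N_bar),
        r_F=tau * p.r_F * p.N_bar ** d.q,
        r_F_max=p.r_F_max,
        a_c_I=p.a_c_I / p.c_w,
        kappa_F=p.kappa_F * p.N_bar,
        k_F=tau * p.k_F * p.c_w,
        delta_N=tau * p.delta_N,
        delta_M=tau * p.delta_M,
        D_c=p.D_c / (p.D_F * p.N_bar),
        k_c=tau * p.k_c * p.N_bar / p.c_w,
        eta=p.eta,
        a_c_II=p.a_c_II / p.c_w,
        delta_c=tau * p.delta_c * p.N_bar * p.rho_bar,
        a_c_III=p.a_c_III * p.c_w,
        k_rho=tau * p.k_rho * p.N_bar / p.rho_bar,
        k_rho_max=p.k_rho_max,
        a_c_IV=p.a_c_IV / p.c_w,
        E=p.E * p.rho_bar ** 2 / (p.xi * p.N_bar),
        nu=p.nu,
        xi=1.0,
        R_rho_const=p.R_rho_const / p.rho_bar,
        N_bar=1.0,
        M_bar=p.M_bar / p.N_bar,
        rho_bar=1.0,
        s=p.s * p.rho_bar ** 2 * p.L / (p.xi * p.N_bar),
        I_w=p.I_w,
        c_w=1.0,
        c_I=p.c_I / p.L,
        c_II=p.c_II / p.L,
        L=1.0,
    )
    d_star = DerivedParameters(
        q=d.q,
        delta_rho=tau * d.delta_rho * p.N_bar * p.rho_bar,
        c_bar=d.c_bar / p.c_w,
    )
    return p_star, d_star, scales


def redimensionalise(
    p_star: DimensionalParameters,
    d_star: DerivedParameters,
    scales: ScalingSet,
) -> tuple[DimensionalParameters, DerivedParameters]:
    """Exact inverse of :func:`nondimensionalise` (round-trip identity)."""
    L = scales.length_scale
    tau = scales.time_scale
    Nb = scales.density_scale_cells
    rb = scales.conc_scale_collagen
    cw = scales.conc_scale_signal
    st = scales.stress_scale
    xi = st * rb / Nb          # stress scale is xi N_bar / rho_bar
    D_F = L ** 2 / (tau * Nb)
    p = DimensionalParameters(
        D_F=D_F * p_star.D_F,
        chi_F=p_star.chi_F * D_F * Nb / cw,
        r_F=p_star.r_F / (tau * Nb ** d_star.q),
        r_F_max=p_star.r_F_max,
        a_c_I=p_star.a_c_I * cw,
        kappa_F=p_star.kappa_F / Nb,
        k_F=p_star.k_F / (tau * cw),
        delta_N=p_star.delta_N / tau,
        delta_M=p_star.delta_M / tau,
        D_c=p_star.D_c * D_F * Nb,
        k_c=p_star.k_c * cw / (tau * Nb),
        eta=p_star.eta,
        a_c_II=p_star.a_c_II * cw,
        delta_c=p_star.delta_c / (tau * Nb * rb),
        a_c_III=p_star.a_c_III / cw,
        k_rho=p_star.k_rho * rb / (tau * Nb),
        k_rho_max=p_star.k_rho_max,
        a_c_IV=p_star.a_c_IV * cw,
        E=p_star.E * xi * Nb / rb ** 2,
        nu=p_star.nu,
        xi=xi * p_star.xi,
        R_rho_const=p_star.R_rho_const * rb,
        N_bar=Nb * p_star.N_bar,
        M_bar=p_star.M_bar * Nb,
        rho_bar=rb * p_star.rho_bar,
        s=p_star.s * xi * Nb / (rb ** 2 * L),
        I_w=p_star.I_w,
        c_w=cw * p_star.c_w,
        c_I=p_star.c_I * L,
        c_II=p_star.c_II * L,
        L=L * p_star.L,
    )
    d = DerivedParameters(
        q=d_star.q,
        delta_rho=d_star.delta_rho / (tau * Nb * rb),
        c_bar=d_star.c_bar * cw,
    )
    return p, d


def parameter_names() -> list[str]:
    """Names of all dimensional parameters (config-file keys)."""
    return [f.name for f in fields(DimensionalParameters)]


def with_overrides(p: DimensionalParameters, **kw: float) -> DimensionalParameters:
    """Copy with field overrides; unknown names raise."""
    known = set(parameter_names())
    for k in kw:
        if k not in known:
            raise KeyError(f"unknown parameter {k!r}")
    return replace(p, **kw)
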
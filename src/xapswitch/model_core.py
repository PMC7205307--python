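"""Rate laws and parameters of the xapABR transporter-feedback switch.

The circuit couples three dynamical variables — mRNA, protein (XapA and
XapB are lumped into one concentration) and intracellular xanthosine — via

* MWC (Monod–Wyman–Changeux) induction of the XapR dimer by xanthosine,
* thermodynamic (quasi-equilibrium) occupancy of the two-site xapAB
  promoter, with transcription from the fully occupied state,
* Michaelis–Menten import/export of xanthosine by XapB, degradation by
  XapA, and linearized non-specific uptake/leakage through the Nup
  transporters.

Everything is available both in dimensional form (M, s) and in the
nondimensional form used throughout the analysis, with time measured in
units of 1/gamma_p and concentrations in units of the XapA Michaelis
constant K_a.

Sign convention for cooperativity: ``deps_coop`` is the *magnitude* of the
favorable XapR–XapR interaction (in units of k_BT), so the doubly occupied
promoter state carries the enhancing Boltzmann factor ``exp(+deps_coop)``.
With the default value 5 this reproduces the bistable regime and the
copy-number scales of the reference scenario; ``deps_coop = 0`` switches
the interaction off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .variants import CircuitVariant

__all__ = [
    "MWCParams",
    "PromoterParams",
    "ExpressionRates",
    "TransportParams",
    "DimensionalParams",
    "NondimParams",
    "SystemState",
    "table1",
    "nondimensionalize",
    "dimensionalize",
    "xapr_active_fraction",
    "promoter_state_weights",
    "promoter_active_probability",
    "mean_mrna",
    "rhs_nondimensional",
    "rhs_dimensional",
]

#: Keys of the flat nondimensional parameter record, in canonical order.
PARAM_KEYS = (
    "rho_m", "gamma_mp", "rho_p", "XapR_R", "c_a",
    "k_beta_i", "k_beta_e", "k_alpha", "k_eta", "xi",
    "K_beta_i", "K_beta_e", "K_chiA", "K_IA", "deps_x", "deps_coop",
)


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def _require_positive(name: str, value: float) -> None:
    _require_finite(name, value)
    if value <= 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class MWCParams:
    """Two-state allosteric induction of the XapR dimer.

    K_chiA: dissociation constant of xanthosine to *active* XapR, in K_a.
    K_IA:   ratio of inactive to active dissociation constants (K_xI/K_xA).
    delta_eps_x: inactive-minus-active conformational energy gap, k_BT.
    XapR_R: total XapR dimer concentration in units of its promoter
            dissociation constant K_XapR.
    """

    K_chiA: float
    K_IA: float
    delta_eps_x: float
    XapR_R: float

    def __post_init__(self) -> None:
        _require_positive("K_chiA", self.K_chiA)
        _require_positive("K_IA", self.K_IA)
        _require_finite("delta_eps_x", self.delta_eps_x)
        _require_positive("XapR_R", self.XapR_R)


@dataclass(frozen=True)
class PromoterParams:
    """Thermodynamic promoter parameters.

    delta_eps_coop: magnitude of the favorable XapR–XapR interaction, k_BT.
    pol_term: polymerase saturation [P]/(K_P + [P]); only meaningful in
        dimensional mode — the nondimensional transcription strength rho_m
        already contains it.
    """

    delta_eps_coop: float
    pol_term: float = 1.0

    def __post_init__(self) -> None:
        _require_finite("delta_eps_coop", self.delta_eps_coop)
        if not (0.0 < self.pol_term <= 1.0):
            raise ValueError(f"pol_term must lie in (0, 1], got {self.pol_term!r}")


@dataclass(frozen=True)
class ExpressionRates:
    rho_m: float     #: nondimensional transcription strength (pol term folded in)
    gamma_mp: float  #: mRNA-to-protein decay ratio gamma_m/gamma_p
    rho_p: float     #: nondimensional translation rate r_p/gamma_p

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))

    @property
    def rho(self) -> float:
        """Lumped expression strength rho = rho_m * rho_p / gamma_mp."""
        return self.rho_m * self.rho_p / self.gamma_mp


@dataclass(frozen=True)
class TransportParams:
    k_beta_i: float  #: XapB import turnover, 1/gamma_p units
    k_beta_e: float  #: XapB export turnover
    K_beta_i: float  #: XapB import Michaelis constant, K_a units
    K_beta_e: float  #: XapB export Michaelis constant
    k_alpha: float   #: XapA degradation turnover
    k_eta: float     #: non-specific (Nup) uptake rate
    xi: float        #: Nup efflux-to-influx asymmetry

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional model parameters (concentrations in M, time in s)."""

    r_m: float        # transcription rate, M^-1 s^-1 (contains gene copy number)
    gamma_m: float    # mRNA decay, s^-1
    r_p: float        # translation rate, s^-1
    gamma_p: float    # protein decay, s^-1
    K_XapR: float     # XapR-promoter dissociation constant, M
    K_P: float        # polymerase-promoter dissociation constant, M
    P_conc: float     # polymerase concentration, M
    K_xA: float       # xanthosine-active XapR dissociation constant, M
    K_xI: float       # xanthosine-inactive XapR dissociation constant, M
    dE_x: float       # conformational energy gap, k_BT
    dE_coop: float    # XapR-XapR interaction magnitude, k_BT
    XapR_tot: float   # total XapR dimer concentration, M
    k_a: float        # XapA turnover, s^-1
    K_a: float        # XapA Michaelis constant, M
    k_bi: float       # XapB import turnover, s^-1
    K_bi: float       # XapB import Michaelis constant, M
    k_be: float       # XapB export turnover, s^-1
    K_be: float       # XapB export Michaelis constant, M
    k_nup: float      # Nup uptake rate, s^-1
    xi: float         # dimensionless efflux asymmetry
    c: float          # extracellular xanthosine concentration, M

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("dE_x", "dE_coop"):
                _require_finite(f.name, v)
            elif f.name == "c":
                _require_finite(f.name, v)
                if v < 0:
                    raise ValueError(f"c must be nonnegative, got {v!r}")
            else:
                _require_positive(f.name, v)

    @property
    def pol_term(self) -> float:
        return self.P_conc / (self.K_P + self.P_conc)


@dataclass(frozen=True)
class NondimParams:
    """The flat nondimensional parameter record (canonical configuration).

    Concentrations are in units of K_a and rates in units of gamma_p; the
    polymerase saturation factor is folded into ``rho_m``.
    """

    rho_m: float
    gamma_mp: float
    rho_p: float
    XapR_R: float
    c_a: float
    k_beta_i: float
    k_beta_e: float
    k_alpha: float
    k_eta: float
    xi: float
    K_beta_i: float
    K_beta_e: float
    K_chiA: float
    K_IA: float
    deps_x: float
    deps_coop: float

    def __post_init__(self) -> None:
        for key in PARAM_KEYS:
            v = getattr(self, key)
            if key in ("deps_x", "deps_coop"):
                _require_finite(key, v)
            elif key == "c_a":
                _require_finite(key, v)
                if v < 0:
                    raise ValueError(f"c_a must be nonnegative, got {v!r}")
            else:
                _require_positive(key, v)

    # -- derived views -----------------------------------------------------
    @property
    def rho(self) -> float:
        """Lumped expression strength rho = rho_m * rho_p / gamma_mp."""
        return self.rho_m * self.rho_p / self.gamma_mp

    @property
    def mwc(self) -> MWCParams:
        return MWCParams(self.K_chiA, self.K_IA, self.deps_x, self.XapR_R)

    @property
    def promoter(self) -> PromoterParams:
        return PromoterParams(self.deps_coop)

    @property
    def expression(self) -> ExpressionRates:
        return ExpressionRates(self.rho_m, self.gamma_mp, self.rho_p)

    @property
    def transport(self) -> TransportParams:
        return TransportParams(self.k_beta_i, self.k_beta_e, self.K_beta_i,
                               self.K_beta_e, self.k_alpha, self.k_eta, self.xi)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NondimParams":
        unknown = set(d) - set(PARAM_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        base = table1().to_dict()
        base.update({k: float(v) for k, v in d.items()})
        return cls(**base)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def with_(self, **overrides: float) -> "NondimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class SystemState:
    """Nondimensional state (concentrations in K_a units, time in 1/gamma_p)."""

    m_a: float
    p_a: float
    x_a: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_a", "p_a", "x_a"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_a, self.p_a, self.x_a], dtype=float)


def table1(**overrides: float) -> NondimParams:
    """The canonical reference parameter set (``Value used`` column).

    Based on gamma_p = 5e-4 s^-1 and K_a = 5e-5 M.  Keyword overrides
    replace individual entries.
    """
    base = NondimParams(
        rho_m=1e-3, gamma_mp=1e1, rho_p=1e2, XapR_R=1.0, c_a=13.0,
        k_beta_i=5e4, k_beta_e=1e3, k_alpha=1e2, k_eta=5e-1, xi=0.8,
        K_beta_i=1e1, K_beta_e=1e2, K_chiA=1e2, K_IA=1e2,
        deps_x=5.0, deps_coop=5.0,
    )
    return base.with_(**overrides) if overrides else base


#: Reference scales accompanying :func:`table1` (protein decay rate in s^-1
#: and XapA Michaelis constant in M).
GAMMA_P_REF = 5e-4
K_A_REF = 5e-5


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def xapr_active_fraction(x_a, mwc: MWCParams, inducer_sites: int = 2):
    """Fraction of XapR dimers in the active conformation (MWC).

    With two xanthosine binding sites per dimer (default),

        f(x) = (1 + x/K_chiA)^2 /
               [(1 + x/K_chiA)^2 + e^{deps_x} (1 + x/(K_chiA K_IA))^2]

    ``inducer_sites=1`` drops the exponents to 1 (single-site variant).
    Accepts scalars or arrays; returns values in (0, 1).
    """
    x = np.asarray(x_a, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("x_a must be finite and nonnegative")
    if inducer_sites not in (1, 2):
        raise ValueError("inducer_sites must be 1 or 2")
    u = x / mwc.K_chiA
    n = inducer_sites
    act = (1.0 + u) ** n
    inact = math.exp(mwc.delta_eps_x) * (1.0 + u / mwc.K_IA) ** n
    out = act / (act + inact)
    return float(out) if np.isscalar(x_a) else out


def promoter_state_weights(xapr_ratio: float, pol_ratio: float,
                           delta_eps_coop: float) -> np.ndarray:
    """Thermodynamic weights of the 8 promoter occupancy states.

    Order: (empty, XapR@1, XapR@2, 2xXapR, P, P+XapR@1, P+XapR@2, P+2xXapR).
    The doubly occupied states carry the cooperative enhancement
    ``exp(+delta_eps_coop)``; the empty state has weight 1.  The partition
    function factorizes: sum(w) = (1 + pol)(1 + 2 r + r^2 e^{deps_coop}).
    """
    r, q = float(xapr_ratio), float(pol_ratio)
    if r < 0 or q < 0:
        raise ValueError("occupancy ratios must be nonnegative")
    coop = r * r * math.exp(delta_eps_coop)
    return np.array([1.0, r, r, coop, q, q * r, q * r, q * coop])


def promoter_active_probability(xapr_active, deps_coop: float,
                                pol_term: float = 1.0,
                                promoter_sites: int = 2,
                                active_policy: str = "fully_occupied_only"):
    """Probability that the promoter is transcribing.

    Default (two XapR sites, only the fully occupied state active):

        p_active = pol_term * r^2 e^{deps_coop} / (1 + 2r + r^2 e^{deps_coop})

    with r the active-XapR occupancy ratio.  ``promoter_sites=1`` gives
    pol_term * r/(1+r); ``active_policy='any_xapr_bound'`` counts every
    XapR-bound state as transcribing at full rate.  In nondimensional mode
    pol_term is 1 (it lives inside rho_m).
    """
    r = np.asarray(xapr_active, dtype=float)
    if np.any(r < 0):
        raise ValueError("xapr_active must be nonnegative")
    if promoter_sites not in (1, 2):
        raise ValueError("promoter_sites must be 1 or 2")
    if active_policy not in ("fully_occupied_only", "any_xapr_bound"):
        raise ValueError(f"unknown active_policy {active_policy!r}")
    if promoter_sites == 1:
        p = r / (1.0 + r)
    else:
        w = r * r * math.exp(deps_coop)
        num = 2.0 * r + w if active_policy == "any_xapr_bound" else w
        p = num / (1.0 + 2.0 * r + w)
    p = pol_term * p
    return float(p) if np.isscalar(xapr_active) else p


def _p_active_of_x(x_a, params: NondimParams, variant: "CircuitVariant | None"):
    """Promoter activity as a function of intracellular xanthosine."""
    from .variants import CircuitVariant  # local import to avoid a cycle

    v = variant if variant is not None else CircuitVariant()
    deps_coop = (v.deps_coop_override if v.deps_coop_override is not None
                 else params.deps_coop)
    f = xapr_active_fraction(x_a, params.mwc, inducer_sites=v.inducer_sites_per_TF)
    return promoter_active_probability(
        params.XapR_R * f, deps_coop,
        promoter_sites=v.promoter_sites, active_policy=v.active_policy)


def mean_mrna(params: NondimParams, x_a: float,
              variant: "CircuitVariant | None" = None) -> float:
    """Mean mRNA concentration (rho_m / gamma_mp) * p_active at fixed x_a.

    This is the stationary mean of the transcription–decay balance and the
    m_a component of every fixed point.
    """
    return params.rho_m / params.gamma_mp * _p_active_of_x(x_a, params, variant)


def _transport_rate(x_a, params: NondimParams, variant: "CircuitVariant | None"):
    """Per-protein net xanthosine flux T(x): XapB import - export - XapA."""
    from .variants import CircuitVariant

    v = variant if variant is not None else CircuitVariant()
    x = np.asarray(x_a, dtype=float)
    T = np.zeros_like(x)
    if not v.xapB_removed:
        T = T + (params.k_beta_i * params.c_a / (params.K_beta_i + params.c_a)
                 - params.k_beta_e * x / (params.K_beta_e + x))
    if not v.xapA_removed:
        T = T - params.k_alpha * x / (1.0 + x)
    return float(T) if np.isscalar(x_a) else T


def rhs_nondimensional(state, params: NondimParams,
                       variant: "CircuitVariant | None" = None) -> np.ndarray:
    """Time derivatives (d m_a, d p_a, d x_a)/d tau of the 3D system.

    d m_a/d tau = rho_m * p_active(x_a) - gamma_mp * m_a
    d p_a/d tau = rho_p * m_a - p_a
    d x_a/d tau = T(x_a) * p_a + k_eta * (c_a - xi * x_a)

    ``state`` may be a :class:`SystemState` or a length-3 array
    (m_a, p_a, x_a).
    """
    y = state.as_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if y.shape != (3,):
        raise ValueError("state must have three components (m_a, p_a, x_a)")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("state components must be finite and nonnegative")
    m, p, x = y
    dm = params.rho_m * _p_active_of_x(x, params, variant) - params.gamma_mp * m
    dp = params.rho_p * m - p
    dx = _transport_rate(x, params, variant) * p + params.k_eta * (params.c_a - params.xi * x)
    return np.array([dm, dp, dx])


def rhs_dimensional(state, params: DimensionalParams) -> np.ndarray:
    """Dimensional twin of :func:`rhs_nondimensional` (d[m], d[p], d[x])/dt in M/s."""
    y = np.asarray(state, dtype=float)
    if y.shape != (3,):
        raise ValueError("state must have three components ([m], [p], [x])")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("state components must be finite and nonnegative")
    m, p, x = y
    mwc = MWCParams(K_chiA=params.K_xA, K_IA=params.K_xI / params.K_xA,
                    delta_eps_x=params.dE_x, XapR_R=params.XapR_tot / params.K_XapR)
    # MWC takes the raw concentration here, so use K_chiA in M directly.
    f = xapr_active_fraction(x / 1.0, mwc)
    p_act = promoter_active_probability(mwc.XapR_R * f, params.dE_coop,
                                        pol_term=params.pol_term)
    dm = params.r_m * p_act - params.gamma_m * m
    dp = params.r_p * m - params.gamma_p * p
    T = (params.k_bi * params.c / (params.K_bi + params.c)
         - params.k_be * x / (params.K_be + x)
         - params.k_a * x / (params.K_a + x))
    dx = T * p + params.k_nup * (params.c - params.xi * x)
    return np.array([dm, dp, dx])


# ---------------------------------------------------------------------------
# scaling maps
# ---------------------------------------------------------------------------

def nondimensionalize(params: DimensionalParams) -> NondimParams:
    """Map dimensional parameters onto the nondimensional record.

    Time is measured in 1/gamma_p, concentrations in K_a; the polymerase
    saturation factor is folded into rho_m.
    """
    gp, Ka = params.gamma_p, params.K_a
    return NondimParams(
        rho_m=params.r_m / (gp * Ka) * params.pol_term,
        gamma_mp=params.gamma_m / gp,
        rho_p=params.r_p / gp,
        XapR_R=params.XapR_tot / params.K_XapR,
        c_a=params.c / Ka,
        k_beta_i=params.k_bi / gp,
        k_beta_e=params.k_be / gp,
        k_alpha=params.k_a / gp,
        k_eta=params.k_nup / gp,
        xi=params.xi,
        K_beta_i=params.K_bi / Ka,
        K_beta_e=params.K_be / Ka,
        K_chiA=params.K_xA / Ka,
        K_IA=params.K_xI / params.K_xA,
        deps_x=params.dE_x,
        deps_coop=params.dE_coop,
    )


def dimensionalize(nd: NondimParams, gamma_p: float = GAMMA_P_REF,
                   K_a: float = K_A_REF, K_XapR: float = 1e-8,
                   P_conc: float = 1e-6, K_P: float = 1e-6) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the reference scales.

    The polymerase split (P_conc, K_P) and K_XapR are free choices that the
    nondimensional record does not constrain; the defaults are plausible
    E. coli magnitudes.  Round-tripping through
    :func:`nondimensionalize` recovers ``nd`` exactly.
    """
    pol = P_conc / (K_P + P_conc)
    return DimensionalParams(
        r_m=nd.rho_m * gamma_p * K_a / pol,
        gamma_m=nd.gamma_mp * gamma_p,
        r_p=nd.rho_p * gamma_p,
        gamma_p=gamma_p,
        K_XapR=K_XapR,
        K_P=K_P,
        P_conc=P_conc,
        K_xA=nd.K_chiA * K_a,
        K_xI=nd.K_IA * nd.K_chiA * K_a,
        dE_x=nd.deps_x,
        dE_coop=nd.deps_coop,
        XapR_tot=nd.XapR_R * K_XapR,
        k_a=nd.k_alpha * gamma_p,
        K_a=K_a,
        k_bi=nd.k_beta_i * gamma_p,
        K_bi=nd.K_beta_i * K_a,
        k_be=nd.k_beta_e * gamma_p,
        K_be=nd.K_beta_e * K_a,
        k_nup=nd.k_eta * gamma_p,
        xi=nd.xi,
        c=nd.c_a * K_a,
    )
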
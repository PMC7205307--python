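"""Structural edits of the circuit: ablations, site counts, activity policy.

A :class:`CircuitVariant` describes which pieces of the wild-type circuit
are present: the XapA degradation enzyme, the XapB transporter, the number
of xanthosine binding sites on the XapR dimer, the number of XapR binding
sites on the promoter, an optional override of the cooperative interaction
energy, and the promoter-activity policy (which occupancy states count as
transcribing).  The default variant is a strict identity — it reproduces
the wild-type rate laws at machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, NamedTuple

import numpy as np

from . import model_core as mc
from .model_core import NondimParams

__all__ = ["CircuitVariant", "RateLaws", "apply_variant", "cooperativity_sweep"]


@dataclass(frozen=True)
class CircuitVariant:
    xapA_removed: bool = False
    xapB_removed: bool = False
    promoter_sites: int = 2
    inducer_sites_per_TF: int = 2
    deps_coop_override: float | None = None
    active_policy: str = "fully_occupied_only"

    def __post_init__(self) -> None:
        if self.promoter_sites not in (1, 2):
            raise ValueError("promoter_sites must be 1 or 2")
        if self.inducer_sites_per_TF not in (1, 2):
            raise ValueError("inducer_sites_per_TF must be 1 or 2")
        if self.active_policy not in ("fully_occupied_only", "any_xapr_bound"):
            raise ValueError(f"unknown active_policy {self.active_policy!r}")
        if self.promoter_sites == 1 and self.deps_coop_override is not None:
            raise ValueError(
                "deps_coop_override is contradictory with promoter_sites=1: "
                "a single-site promoter has no XapR-XapR interaction")

    def with_(self, **overrides) -> "CircuitVariant":
        return replace(self, **overrides)


class RateLaws(NamedTuple):
    """Bundle of variant-edited rate-law callables (all vectorized in x_a)."""

    active_fraction: Callable      # MWC active fraction f(x)
    p_active: Callable             # promoter activity p_active(x)
    dp_active_dx: Callable         # analytic d p_active / d x
    transport: Callable            # per-protein net flux T(x)
    dtransport_dx: Callable        # analytic d T / d x
    rhs: Callable                  # full 3D right-hand side rhs(state)
    params: NondimParams
    variant: CircuitVariant


def apply_variant(variant: CircuitVariant, params: NondimParams) -> RateLaws:
    """Build the rate-law bundle for a circuit variant.

    ``inducer_sites_per_TF=1`` drops the MWC exponents from 2 to 1;
    ``promoter_sites=1`` replaces the two-site promoter activity by
    r/(1+r); removals zero the corresponding xanthosine-flux terms;
    ``active_policy='any_xapr_bound'`` counts every XapR-bound state as
    transcribing at the full rate.
    """
    p = params
    v = variant
    deps_coop = v.deps_coop_override if v.deps_coop_override is not None else p.deps_coop
    n_sites = v.inducer_sites_per_TF
    edx = math.exp(p.deps_x)
    ecoop = math.exp(deps_coop)

    def active_fraction(x):
        return mc.xapr_active_fraction(x, p.mwc, inducer_sites=n_sites)

    def dfraction_dx(x):
        x = np.asarray(x, dtype=float)
        u = x / p.K_chiA
        a = (1.0 + u) ** n_sites
        b = edx * (1.0 + u / p.K_IA) ** n_sites
        da = n_sites * (1.0 + u) ** (n_sites - 1) / p.K_chiA
        db = edx * n_sites * (1.0 + u / p.K_IA) ** (n_sites - 1) / (p.K_IA * p.K_chiA)
        return (da * b - a * db) / (a + b) ** 2

    def p_active(x):
        f = active_fraction(x)
        return mc.promoter_active_probability(
            p.XapR_R * f, deps_coop,
            promoter_sites=v.promoter_sites, active_policy=v.active_policy)

    def dp_active_dr(r):
        r = np.asarray(r, dtype=float)
        if v.promoter_sites == 1:
            return 1.0 / (1.0 + r) ** 2
        D = 1.0 + 2.0 * r + r * r * ecoop
        if v.active_policy == "any_xapr_bound":
            return (2.0 + 2.0 * r * ecoop) / D ** 2
        return 2.0 * r * ecoop * (1.0 + r) / D ** 2

    def dp_active_dx(x):
        r = p.XapR_R * active_fraction(x)
        return dp_active_dr(r) * p.XapR_R * dfraction_dx(x)

    def transport(x):
        return mc._transport_rate(x, p, v)

    def dtransport_dx(x):
        x = np.asarray(x, dtype=float)
        d = np.zeros_like(x)
        if not v.xapB_removed:
            d = d - p.k_beta_e * p.K_beta_e / (p.K_beta_e + x) ** 2
        if not v.xapA_removed:
            d = d - p.k_alpha / (1.0 + x) ** 2
        return d

    def rhs(state):
        return mc.rhs_nondimensional(state, p, v)

    return RateLaws(active_fraction, p_active, dp_active_dx,
                    transport, dtransport_dx, rhs, p, v)


def cooperativity_sweep(params: NondimParams, deps_coop_values,
                        variant: CircuitVariant | None = None) -> list[dict]:
    """Fixed-point structure as a function of the interaction energy.

    Runs the fixed-point search with ``deps_coop_override`` set to each
    value in turn and reports, per value, the number of fixed points and
    whether the system is bistable (three fixed points, outer two stable).
    """
    from .deterministic import find_fixed_points

    base = variant if variant is not None else CircuitVariant()
    out = []
    for dc in deps_coop_values:
        v = base.with_(deps_coop_override=float(dc))
        fps = find_fixed_points(params, v)
        out.append({
            "deps_coop": float(dc),
            "n_fixed_points": len(fps),
            "bistable": len(fps) == 3,
            "fixed_points": fps,
        })
    return out
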
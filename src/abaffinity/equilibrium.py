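"""Bivalent antibody-antigen solution equilibrium (Goldberg analysis).

Given total and equilibrium species concentrations from a solution
measurement, this module computes:

* ``p``, the reacted-antigen-site fraction, from the free-antigen ratio:
  ``c_ag = c_g * (1 - p)**f`` with ``f`` the antibody valence (2 for IgG);
* the Goldberg association constant (M^-1), a site-level mass-action
  constant for an f-valent binder:

      K = f * M_a * p / (4 * c_a * (1 - p) * (1 - p*f*c_g*M_a / (2*c_a*M_g)))

  with mass concentrations ``c_a``, ``c_g`` in g/L and molar masses in
  g/mol.  In molar variables this reduces to
  ``K = f*p / (4*(1-p)*(A - p*f*G/2))`` with A, G the total molar
  concentrations, i.e. K = [bond] / ([free antigen site][free antibody
  site]) under random site reaction;
* the mole-fraction constant ``K_a = K * [water]`` (default 55.34 M) and
  the binding free energy ``dG = -R*T*ln(K_a)`` with R = 1.987 cal/K/mol.

A forward simulator generates species concentrations from a known site
constant for parameter-recovery studies.  Its default model is the same
site-reaction statistics the Goldberg inversion assumes (so simulate ->
analyze is an exact round trip, for any arm-cooperativity skew rho); the
independent-sites mass-action model ([AbAg] = 2K[Ab][Ag],
[AbAg2] = rho K^2 [Ab][Ag]^2) is available as ``model="mass_action"`` —
under it the Goldberg inversion returns an effective constant that differs
from the site constant (estimator-model mismatch), which is itself useful
to quantify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SolverError, ValidationError

R_CAL = 1.987               # cal / (K mol)
DEFAULT_TEMPERATURE = 309.0  # K
DEFAULT_WATER_MOLARITY = 55.34  # mol/L, pure water near standard conditions
DEFAULT_MASS_AB = 147.0     # kDa, IgG
DEFAULT_MASS_AG = 86.4      # kDa, glycosylated HER2 ectodomain


@dataclass
class SpeciesConcentrations:
    """Totals and equilibrium species of one antibody-antigen mixture (uM)."""

    total_ab_uM: float
    total_ag_uM: float
    complex1_uM: float            # 1:1 antigen:antibody
    complex2_uM: float            # 2:1 antigen:antibody
    free_ab_uM: float
    free_ag_uM: float
    mass_ab_kDa: float = DEFAULT_MASS_AB
    mass_ag_kDa: float = DEFAULT_MASS_AG
    f: int = 2
    label: str = ""

    def __post_init__(self):
        for name in (
            "total_ab_uM", "total_ag_uM", "complex1_uM",
            "complex2_uM", "free_ab_uM", "free_ag_uM",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.f < 1 or int(self.f) != self.f:
            raise ValidationError("antibody valence f must be a positive integer")

    def mass_balance_residuals(self) -> tuple[float, float]:
        """Relative mass-balance misfit (antibody, antigen)."""
        ab = (self.free_ab_uM + self.complex1_uM + self.complex2_uM) / self.total_ab_uM - 1
        ag = (self.free_ag_uM + self.complex1_uM + 2 * self.complex2_uM) / self.total_ag_uM - 1
        return ab, ag

    def check_mass_balance(self, tol: float = 0.05, policy: str = "warn") -> None:
        ab, ag = self.mass_balance_residuals()
        worst = max(abs(ab), abs(ag))
        if worst > tol:
            msg = (
                f"mass balance violated beyond {tol:.0%}: "
                f"antibody {ab:+.2%}, antigen {ag:+.2%}"
            )
            if policy == "error":
                raise ValidationError(msg)
            warnings.warn(msg)

    @property
    def total_mass_conc_gL(self) -> float:
        """Total protein mass concentration C_T (g/L)."""
        return (
            self.total_ab_uM * self.mass_ab_kDa
            + self.total_ag_uM * self.mass_ag_kDa
        ) * 1e-3

    def species_mass_fractions(self) -> dict[str, float]:
        """Mass concentration of each species as a fraction of C_T."""
        m1 = self.mass_ab_kDa + self.mass_ag_kDa
        m2 = self.mass_ab_kDa + 2 * self.mass_ag_kDa
        ct = self.total_mass_conc_gL
        return {
            "free_ag": self.free_ag_uM * self.mass_ag_kDa * 1e-3 / ct,
            "free_ab": self.free_ab_uM * self.mass_ab_kDa * 1e-3 / ct,
            "complex1": self.complex1_uM * m1 * 1e-3 / ct,
            "complex2": self.complex2_uM * m2 * 1e-3 / ct,
        }


@dataclass
class BindingEquilibrium:
    """Derived equilibrium quantities of a mixture."""

    p: float                  # reacted antigen-site fraction
    k_molar: float            # M^-1
    k_a: float                # mole fraction^-1
    delta_g: float            # kcal/mol
    temperature: float
    water_molarity: float
    species: SpeciesConcentrations | None = None


def reacted_site_fraction(
    free_ag: float, total_ag: float, f: int = 2
) -> float:
    """p = 1 - (c_ag/c_g)^(1/f); any consistent concentration unit."""
    if f < 1:
        raise ValidationError("valence f must be >= 1")
    if total_ag <= 0:
        raise ValidationError("total antigen must be positive")
    if free_ag > total_ag:
        raise ValidationError(
            f"free antigen ({free_ag}) exceeds total ({total_ag})"
        )
    if free_ag == 0:
        warnings.warn("free antigen is zero: p = 1 boundary (saturation)")
        return 1.0
    return 1.0 - (free_ag / total_ag) ** (1.0 / f)


def goldberg_constant(
    p: float,
    c_a: float,
    c_g: float,
    mass_ab: float,
    mass_ag: float,
    f: int = 2,
) -> float:
    """Goldberg association constant (M^-1) from the reacted-site fraction.

    ``c_a``/``c_g`` are total mass concentrations in g/L; ``mass_ab``/
    ``mass_ag`` in g/mol.
    """
    if not 0 < p < 1:
        raise DomainError(f"p must lie strictly in (0, 1), got {p}")
    if min(c_a, c_g, mass_ab, mass_ag) <= 0:
        raise ValidationError("concentrations and masses must be positive")
    bracket = 1.0 - p * f * c_g * mass_ab / (2.0 * c_a * mass_ag)
    if bracket <= 0:
        raise DomainError(
            "over-saturated inputs: free antibody-site term is non-positive "
            f"(1 - p*f*c_g*M_a/(2*c_a*M_g) = {bracket:.4g})"
        )
    return f * mass_ab * p / (4.0 * c_a * (1.0 - p) * bracket)


def goldberg_constant_molar(
    p: float, total_ab_M: float, total_ag_M: float, f: int = 2
) -> float:
    """Same constant from molar totals: K = f*p / (4*(1-p)*(A - p*f*G/2))."""
    denom = total_ab_M - p * f * total_ag_M / 2.0
    if denom <= 0:
        raise DomainError("over-saturated inputs: no free antibody sites")
    if not 0 < p < 1:
        raise DomainError(f"p must lie strictly in (0, 1), got {p}")
    return f * p / (4.0 * (1.0 - p) * denom)


def to_mole_fraction(
    k_molar: float, water_molarity: float = DEFAULT_WATER_MOLARITY
) -> float:
    """Convert a molar association constant to mole-fraction units."""
    if k_molar <= 0:
        raise ValidationError("K must be positive")
    return k_molar * water_molarity


def delta_g_from_ka(
    k_a: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """dG = -R*T*ln(K_a) in kcal/mol (K_a in mole-fraction units)."""
    if k_a <= 0:
        raise ValidationError("K_a must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return -R_CAL * temperature * np.log(k_a) / 1000.0


def analyze_mixture(
    species: SpeciesConcentrations,
    temperature: float = DEFAULT_TEMPERATURE,
    water_molarity: float = DEFAULT_WATER_MOLARITY,
    mass_balance_tol: float = 0.05,
    mass_balance_policy: str = "warn",
) -> BindingEquilibrium:
    """Chain p -> K -> K_a -> dG for one measured mixture."""
    species.check_mass_balance(mass_balance_tol, mass_balance_policy)
    p = reacted_site_fraction(species.free_ag_uM, species.total_ag_uM, species.f)
    c_a = species.total_ab_uM * 1e-6 * species.mass_ab_kDa * 1e3   # g/L
    c_g = species.total_ag_uM * 1e-6 * species.mass_ag_kDa * 1e3
    k = goldberg_constant(
        p, c_a, c_g, species.mass_ab_kDa * 1e3, species.mass_ag_kDa * 1e3, species.f
    )
    k_a = to_mole_fraction(k, water_molarity)
    dg = delta_g_from_ka(k_a, temperature)
    return BindingEquilibrium(p, k, k_a, dg, temperature, water_molarity, species)


def _arm_occupancy_split(
    total_ab: float, bound_ag: float, rho: float
) -> tuple[float, float, float]:
    """Distribute bound antigen over bivalent antibody arms.

    Quasi-chemical weights (1, 2x, rho*x^2) for 0/1/2 occupied arms; x is
    solved so the mean occupancy matches ``bound_ag / total_ab``.  rho = 1
    gives the independent binomial split; rho < 1 penalises and rho > 1
    favours double occupancy at fixed total bound antigen.
    """
    t = bound_ag / total_ab
    if not 0 <= t < 2:
        raise DomainError(f"bound antigen per antibody must be in [0, 2), got {t}")
    if t == 0:
        return total_ab, 0.0, 0.0
    if rho <= 0:
        if t >= 1:
            raise DomainError("rho = 0 cannot accommodate more than one antigen per antibody")
        x = t / (2.0 * (1.0 - t))
        w = np.array([1.0, 2.0 * x, 0.0])
    else:
        # rho*(2-t)*x^2 + 2*(1-t)*x - t = 0, positive root
        a, b, c = rho * (2.0 - t), 2.0 * (1.0 - t), -t
        x = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        w = np.array([1.0, 2.0 * x, rho * x * x])
    w = w / w.sum()
    return total_ab * w[0], total_ab * w[1], total_ab * w[2]


def simulate_equilibrium(
    k_site: float,
    total_ab_uM: float,
    total_ag_uM: float,
    f: int = 2,
    rho: float = 1.0,
    mass_ab_kDa: float = DEFAULT_MASS_AB,
    mass_ag_kDa: float = DEFAULT_MASS_AG,
    model: str = "goldberg",
    label: str = "",
) -> SpeciesConcentrations:
    """Forward-simulate an equilibrium mixture from a known site constant.

    ``model="goldberg"`` (default) uses the same random site-reaction
    statistics the Goldberg inversion assumes: p solves
    ``K = f*p / (4*(1-p)*(A - p*f*G/2))``, free antigen is ``G*(1-p)**f``,
    and the bound antigen is distributed over antibody arms with the
    rho-skewed quasi-chemical split.  ``model="mass_action"`` solves the
    independent-sites law [AbAg] = 2K[Ab][Ag], [AbAg2] = rho*K^2[Ab][Ag]^2
    by bounded root finding on the mass balances (rel. tolerance 1e-12).
    """
    if k_site < 0:
        raise ValidationError("K_site must be non-negative")
    if total_ab_uM <= 0 or total_ag_uM <= 0:
        raise ValidationError("totals must be positive")
    A = total_ab_uM * 1e-6
    G = total_ag_uM * 1e-6

    if k_site == 0:
        return SpeciesConcentrations(
            total_ab_uM, total_ag_uM, 0.0, 0.0, total_ab_uM, total_ag_uM,
            mass_ab_kDa, mass_ag_kDa, f, label,
        )

    if model == "goldberg":
        p_max = min(1.0, 2.0 * A / (f * G)) * (1 - 1e-15)

        def resid_p(p):
            return f * p - k_site * 4.0 * (1.0 - p) * (A - p * f * G / 2.0)

        try:
            p = brentq(resid_p, 0.0, p_max, xtol=1e-30, rtol=8.9e-16, maxiter=300)
        except ValueError as exc:
            raise SolverError(f"no root for reacted-site fraction: {exc}") from exc
        g = G * (1.0 - p) ** f
        bound = G - g
        free_ab, c1, c2 = _arm_occupancy_split(A, bound, rho)
    elif model == "mass_action":
        def free_ab_of(g):
            return A / (1.0 + 2.0 * k_site * g + rho * (k_site * g) ** 2)

        def resid_g(g):
            a = free_ab_of(g)
            return g + 2.0 * k_site * a * g + 2.0 * rho * k_site ** 2 * a * g * g - G

        try:
            g = brentq(resid_g, G * 1e-30, G, xtol=1e-30, rtol=8.9e-16, maxiter=300)
        except ValueError as exc:
            raise SolverError(f"free-antigen root finding failed: {exc}") from exc
        free_ab = free_ab_of(g)
        c1 = 2.0 * k_site * free_ab * g
        c2 = rho * k_site ** 2 * free_ab * g * g
    else:
        raise ValidationError(f"unknown model {model!r}")

    return SpeciesConcentrations(
        total_ab_uM, total_ag_uM,
        c1 * 1e6, c2 * 1e6, free_ab * 1e6, g * 1e6,
        mass_ab_kDa, mass_ag_kDa, f, label,
    )


def species_from_gL(
    total_ab_gL: float,
    total_ag_gL: float,
    complex1_gL: float,
    complex2_gL: float,
    free_ab_gL: float,
    free_ag_gL: float,
    mass_ab_kDa: float = DEFAULT_MASS_AB,
    mass_ag_kDa: float = DEFAULT_MASS_AG,
    f: int = 2,
    label: str = "",
) -> SpeciesConcentrations:
    """Build species from mass concentrations (g/L); exact unit round trip."""
    m1 = mass_ab_kDa + mass_ag_kDa
    m2 = mass_ab_kDa + 2 * mass_ag_kDa
    to_uM = lambda c_gL, m_kDa: c_gL / m_kDa * 1e3
    return SpeciesConcentrations(
        to_uM(total_ab_gL, mass_ab_kDa),
        to_uM(total_ag_gL, mass_ag_kDa),
        to_uM(complex1_gL, m1),
        to_uM(complex2_gL, m2),
        to_uM(free_ab_gL, mass_ab_kDa),
        to_uM(free_ag_gL, mass_ag_kDa),
        mass_ab_kDa, mass_ag_kDa, f, label,
    )
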
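"""Mass-action models of protein–polynucleotide binding competition.

A protein E binds a labeled ligand P and an unlabeled competitor D.  In the
*classic* picture the EP complex dissociates at an intrinsic rate k_neg1P
regardless of how much competitor is present; the competitor only captures
free protein.  In the *direct transfer* picture a competitor can partially
invade the occupied binding site and displace the resident ligand through a
short-lived ternary intermediate, adding a second-order exchange channel
EP + D -> ED + P with rate constant k_thetaD.

Two deterministic ODE schemes are provided:

* ``simplified`` — species {E, P, D, EP, ED}; the ternary intermediate is
  assumed too transient to accumulate, so transfer appears as a single
  bimolecular step.
* ``complete`` — the stable complexes additionally exchange with partially
  associated states (EP*, ED*) which can accept a second polynucleotide to
  form transient ternary species (D·EP*, P·ED*).  In the limit where the
  partial states open and close much faster than every other first-order
  process, the complete scheme collapses onto the simplified one.

All concentrations are molar, all times are seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "RateConstants",
    "PartialStateRates",
    "ReactionTotals",
    "SpeciesState",
    "TimeCourse",
    "KineticsError",
    "IntegrationError",
    "ThermodynamicInconsistencyWarning",
    "simulate_scheme",
    "equilibrium_state",
    "predicted_koff",
    "flux_partition",
    "complete_rates_from_effective",
]

SIMPLIFIED_SPECIES = ("E", "P", "D", "EP", "ED")
COMPLETE_SPECIES = SIMPLIFIED_SPECIES + ("EPs", "EDs", "T_DEP", "T_PED")


class KineticsError(ValueError):
    """Invalid kinetic model input."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed to converge."""


class ThermodynamicInconsistencyWarning(UserWarning):
    """The transfer equilibrium constant contradicts the binding equilibria."""


@dataclass(frozen=True)
class PartialStateRates:
    """First-order rates governing the partially associated states.

    ``nu_open`` is EP -> EP* (site breathing open), ``nu_close`` is
    EP* -> EP; the same pair governs ED <-> ED*.  ``k_ternary_on`` is the
    bimolecular rate at which a free polynucleotide docks onto a partially
    open complex to form a ternary species; ``k_ternary_off`` is the rate at
    which a ternary species sheds either of its polynucleotides.
    """

    nu_open: float
    nu_close: float
    k_ternary_on: float
    k_ternary_off: float

    def __post_init__(self) -> None:
        for name in ("nu_open", "nu_close", "k_ternary_on", "k_ternary_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the competition scheme.

    Parameters
    ----------
    k1P, k1D : float
        Association rate constants of ligand and competitor (M^-1 s^-1).
    k_neg1P, k_neg1D : float
        Intrinsic dissociation rate constants of EP and ED (s^-1).
    k_thetaD : float
        Direct-transfer rate constant for EP + D -> ED + P (M^-1 s^-1).
    k_thetaP : float
        Direct-transfer rate constant for ED + P -> EP + D (M^-1 s^-1).
    partial : PartialStateRates, optional
        Required for the complete scheme.
    """

    k1P: float
    k_neg1P: float
    k1D: float
    k_neg1D: float
    k_thetaD: float = 0.0
    k_thetaP: float = 0.0
    partial: PartialStateRates | None = None

    def __post_init__(self) -> None:
        for name in ("k1P", "k_neg1P", "k1D", "k_neg1D", "k_thetaD", "k_thetaP"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def K_dP(self) -> float:
        """Equilibrium dissociation constant of EP (M)."""
        if self.k1P <= 0:
            return np.inf
        return self.k_neg1P / self.k1P

    @property
    def K_dD(self) -> float:
        """Equilibrium dissociation constant of ED (M)."""
        if self.k1D <= 0:
            return np.inf
        return self.k_neg1D / self.k1D

    @classmethod
    def self_competition(
        cls,
        k1: float,
        k_neg1: float,
        k_theta: float,
        partial: PartialStateRates | None = None,
    ) -> "RateConstants":
        """Ligand and competitor are the same chemical species."""
        return cls(
            k1P=k1, k_neg1P=k_neg1, k1D=k1, k_neg1D=k_neg1,
            k_thetaD=k_theta, k_thetaP=k_theta, partial=partial,
        )

    def check_thermodynamic_consistency(
        self, rtol: float = 1e-6, strict: bool = False
    ) -> bool:
        """Check k_thetaD / k_thetaP == K_dP / K_dD.

        The transfer step EP + D <-> ED + P closes a thermodynamic cycle with
        the two binding equilibria, so its equilibrium constant is fixed by
        the ratio of the K_d values.  Returns True when consistent.  When
        inconsistent, warns by default and raises in strict mode; fitted
        transfer constants are typically unconstrained this way, so the
        check is advisory.
        """
        if self.k_thetaD == 0 and self.k_thetaP == 0:
            return True
        if self.k_thetaP == 0 or not np.isfinite(self.K_dD) or self.K_dD == 0:
            consistent = False
        else:
            lhs = self.k_thetaD / self.k_thetaP
            rhs = self.K_dP / self.K_dD
            consistent = np.isclose(lhs, rhs, rtol=rtol)
        if not consistent:
            msg = (
                "transfer equilibrium k_thetaD/k_thetaP does not match "
                "K_dP/K_dD; equilibria will depend on the transfer channel"
            )
            if strict:
                raise KineticsError(msg)
            warnings.warn(msg, ThermodynamicInconsistencyWarning, stacklevel=2)
        return consistent


@dataclass(frozen=True)
class ReactionTotals:
    """Conserved totals: protein functional units, labeled ligand, competitor (M)."""

    E_total: float
    P_total: float
    D_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E_total", "P_total", "D_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations of every species at one instant (M)."""

    E: float
    P: float
    D: float
    EP: float
    ED: float
    EPs: float = 0.0
    EDs: float = 0.0
    T_DEP: float = 0.0  # ternary D·EP*
    T_PED: float = 0.0  # ternary P·ED*

    @property
    def E_total(self) -> float:
        return (self.E + self.EP + self.ED + self.EPs + self.EDs
                + self.T_DEP + self.T_PED)

    @property
    def P_total(self) -> float:
        return self.P + self.EP + self.EPs + self.T_DEP + self.T_PED

    @property
    def D_total(self) -> float:
        return self.D + self.ED + self.EDs + self.T_DEP + self.T_PED

    def bound_fraction_P(self) -> float:
        """Fraction of labeled ligand in a protein complex."""
        tot = self.P_total
        return 0.0 if tot == 0 else (tot - self.P) / tot


@dataclass
class TimeCourse:
    """Deterministic trajectory of the scheme on a time grid."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...]
    rates: RateConstants
    totals: ReactionTotals
    variant: str = "simplified"
    meta: dict = field(default_factory=dict)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(species)]

    def state_at(self, i: int) -> SpeciesState:
        row = dict(zip(self.species, self.concentrations[i]))
        return SpeciesState(**row)

    def bound_fraction_P(self) -> np.ndarray:
        """Fraction of labeled ligand bound, per timepoint."""
        if self.totals.P_total == 0:
            return np.zeros_like(self.times)
        return (self.totals.P_total - self["P"]) / self.totals.P_total


def _simplified_rhs(t, y, k):
    E, P, D, EP, ED = y
    assoc_P = k.k1P * E * P
    assoc_D = k.k1D * E * D
    diss_P = k.k_neg1P * EP
    diss_D = k.k_neg1D * ED
    transfer_D = k.k_thetaD * EP * D  # EP + D -> ED + P
    transfer_P = k.k_thetaP * ED * P  # ED + P -> EP + D
    dEP = assoc_P - diss_P - transfer_D + transfer_P
    dED = assoc_D - diss_D + transfer_D - transfer_P
    dE = -assoc_P - assoc_D + diss_P + diss_D
    dP = -assoc_P + diss_P + transfer_D - transfer_P
    dD = -assoc_D + diss_D - transfer_D + transfer_P
    return [dE, dP, dD, dEP, dED]


def _complete_rhs(t, y, k):
    E, P, D, EP, ED, EPs, EDs, T_DEP, T_PED = y
    ps = k.partial
    assoc_P = k.k1P * E * P
    assoc_D = k.k1D * E * D
    diss_P = k.k_neg1P * EP
    diss_D = k.k_neg1D * ED
    open_P = ps.nu_open * EP
    close_P = ps.nu_close * EPs
    open_D = ps.nu_open * ED
    close_D = ps.nu_close * EDs
    # each ternary connects (EPs + D) and (EDs + P) symmetrically
    tdep_form_l = ps.k_ternary_on * EPs * D
    tdep_form_r = ps.k_ternary_on * EDs * P
    tdep_break = ps.k_ternary_off * T_DEP  # splits either way, half each
    tped_form_l = ps.k_ternary_on * EPs * D
    tped_form_r = ps.k_ternary_on * EDs * P
    tped_break = ps.k_ternary_off * T_PED

    dE = -assoc_P - assoc_D + diss_P + diss_D
    dEP = assoc_P - diss_P - open_P + close_P
    dED = assoc_D - diss_D - open_D + close_D
    dEPs = (open_P - close_P - tdep_form_l - tped_form_l
            + 0.5 * tdep_break + 0.5 * tped_break)
    dEDs = (open_D - close_D - tdep_form_r - tped_form_r
            + 0.5 * tdep_break + 0.5 * tped_break)
    dT_DEP = tdep_form_l + tdep_form_r - tdep_break
    dT_PED = tped_form_l + tped_form_r - tped_break
    dP = -assoc_P + diss_P - tdep_form_r - tped_form_r \
        + 0.5 * tdep_break + 0.5 * tped_break
    dD = -assoc_D + diss_D - tdep_form_l - tped_form_l \
        + 0.5 * tdep_break + 0.5 * tped_break
    return [dE, dP, dD, dEP, dED, dEPs, dEDs, dT_DEP, dT_PED]


def complete_rates_from_effective(
    rates: RateConstants,
    nu_open: float,
    nu_close: float,
    k_ternary_off: float,
) -> RateConstants:
    """Build complete-scheme rates whose fast-partial-state limit matches ``rates``.

    With an open-state occupancy f = nu_open/(nu_open + nu_close) and two
    parallel ternary channels each resolving to either side with probability
    1/2, the effective transfer constant is f * k_ternary_on, so
    k_ternary_on = k_thetaD / f.  Symmetric transfer (k_thetaD == k_thetaP)
    is required by the symmetric ternary topology.
    """
    if rates.k_thetaD != rates.k_thetaP:
        raise KineticsError(
            "the symmetric complete-scheme topology requires k_thetaD == k_thetaP"
        )
    f_open = nu_open / (nu_open + nu_close)
    k_on = rates.k_thetaD / f_open if rates.k_thetaD > 0 else 0.0
    partial = PartialStateRates(
        nu_open=nu_open, nu_close=nu_close,
        k_ternary_on=k_on, k_ternary_off=k_ternary_off,
    )
    return RateConstants(
        k1P=rates.k1P, k_neg1P=rates.k_neg1P,
        k1D=rates.k1D, k_neg1D=rates.k_neg1D,
        k_thetaD=rates.k_thetaD, k_thetaP=rates.k_thetaP,
        partial=partial,
    )


def simulate_scheme(
    rates: RateConstants,
    totals: ReactionTotals,
    times: np.ndarray,
    variant: Literal["simplified", "complete"] = "simplified",
    y0: SpeciesState | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Integrate the chosen reaction scheme over ``times``.

    Starts from all species free unless ``y0`` is given (e.g. a
    pre-equilibrated complex for a chase experiment).  Raises
    :class:`IntegrationError` if the solver fails rather than returning NaNs.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise KineticsError("times must be nonempty")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise KineticsError("times must be nonnegative and nondecreasing")
    if variant == "complete" and rates.partial is None:
        raise KineticsError("complete scheme requires partial-state rate constants")
    if variant not in ("simplified", "complete"):
        raise KineticsError(f"unknown scheme variant {variant!r}")

    species = SIMPLIFIED_SPECIES if variant == "simplified" else COMPLETE_SPECIES
    if y0 is None:
        start = [totals.E_total, totals.P_total, totals.D_total, 0.0, 0.0]
        if variant == "complete":
            start += [0.0, 0.0, 0.0, 0.0]
    else:
        start = [getattr(y0, s) for s in species]

    rhs = _simplified_rhs if variant == "simplified" else _complete_rhs
    t0, t1 = float(times[0]), float(times[-1])
    if t1 == t0:
        sol_y = np.tile(np.asarray(start)[:, None], (1, times.size))
    else:
        sol = solve_ivp(
            rhs, (t0, t1), start, t_eval=times, args=(rates,),
            method=method, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}")
        sol_y = sol.y
    conc = np.clip(sol_y.T, 0.0, None)
    return TimeCourse(
        times=times, concentrations=conc, species=species,
        rates=rates, totals=totals, variant=variant,
        meta={"method": method, "rtol": rtol, "atol": atol},
    )


def equilibrium_state(rates: RateConstants, totals: ReactionTotals) -> SpeciesState:
    """Closed-form/root-found equilibrium of the simplified scheme.

    Equilibrium is set by the two binding constants only; a transfer channel
    satisfying detailed balance cannot shift it.  Solves the conservation
    relation for free protein by bracketed root finding.
    """
    KdP, KdD = rates.K_dP, rates.K_dD
    Et, Pt, Dt = totals.E_total, totals.P_total, totals.D_total

    def bound(E, Xt, Kd):
        # ligand bound when protein free conc is E
        if not np.isfinite(Kd):
            return 0.0
        if Kd == 0:
            return Xt if E > 0 else 0.0
        return Xt * E / (Kd + E)

    def residual(E):
        return E + bound(E, Pt, KdP) + bound(E, Dt, KdD) - Et

    if Et == 0:
        E_free = 0.0
    elif residual(0.0) >= 0:
        E_free = 0.0
    else:
        E_free = brentq(residual, 0.0, Et, xtol=1e-30, rtol=1e-14)
    EP = bound(E_free, Pt, KdP)
    ED = bound(E_free, Dt, KdD)
    # infinite-affinity edge: protein partitions up to stoichiometric limits
    if KdP == 0 or KdD == 0:
        EP = min(EP, Pt)
        ED = min(ED, Dt)
    return SpeciesState(E=E_free, P=Pt - EP, D=Dt - ED, EP=EP, ED=ED)


def predicted_koff(rates: RateConstants, D_free: float, P_free: float) -> float:
    """Apparent dissociation rate of the labeled complex during a chase.

    When the EP complex dissociates intrinsically, the freed protein is
    either captured by competitor (association rate k1D*D) or rebinds the
    labeled ligand (k1P*P); only captured dissociations register as signal
    loss.  Direct transfer adds an uncapturable channel k_thetaD*D::

        koff_obs(D) = k_neg1P * k1D*D / (k1D*D + k1P*P_free) + k_thetaD * D

    At D = 0 every dissociation is followed by rebinding of the trace
    labeled ligand, so no net decay is observed.
    """
    if D_free < 0 or P_free < 0:
        raise KineticsError("free concentrations must be >= 0")
    capture = rates.k1D * D_free
    rebind = rates.k1P * P_free
    if capture == 0 and rebind == 0:
        classic = rates.k_neg1P if D_free > 0 else 0.0
    else:
        classic = rates.k_neg1P * capture / (capture + rebind) if capture > 0 else 0.0
    return classic + rates.k_thetaD * D_free


def flux_partition(k_neg1: float, k_theta: float, D: float) -> float:
    """Proportion of protein translocations that proceed by direct transfer.

    At competitor (effective) molarity D the transfer pathway carries flux
    k_theta*D against the classic pathway's k_neg1, giving
    k_theta*D / (k_theta*D + k_neg1).  Equals 0.5 at D = k_neg1/k_theta.
    """
    if k_neg1 < 0 or k_theta < 0 or D < 0:
        raise KineticsError("flux_partition arguments must be >= 0")
    transfer = k_theta * D
    if transfer == 0 and k_neg1 == 0:
        raise KineticsError("flux partition undefined when both pathway fluxes are zero")
    return transfer / (transfer + k_neg1)
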
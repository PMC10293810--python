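"""Fluorescence-polarization competitive-dissociation (FPCD) analysis.

The experimental strategy this pipeline implements:

1. a trace amount of fluorescently labeled ligand is pre-equilibrated with
   just enough protein to saturate binding;
2. unlabeled competitor is added at a range of concentrations to start the
   chase, and polarization is read repeatedly in a plate reader (readings
   before the initiation–measurement dead time, ~90 s, do not exist);
3. each time course is normalized to the global polarization range across
   all competitor concentrations, giving fraction of initial complex
   remaining, and fit with a one-phase exponential decay;
4. the apparent off-rates (initial slopes, k_off_obs) are regressed against
   competitor concentration with a classic-competition model and a
   direct-transfer model, compared by the Bayesian Information Criterion.

Also provides equilibrium binding-isotherm fitting (standard 1:1, Hill, and
ligand-depletion quadratic forms) and FP stoichiometry breakpoint fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

__all__ = [
    "PlateTimeCourseSet",
    "NormalizedDecay",
    "ExponentialFit",
    "KoffProfile",
    "CompetitionFitResult",
    "KdFit",
    "StoichiometryFit",
    "DegenerateDataError",
    "normalize_polarization",
    "fit_exponential_decay",
    "koff_obs_from_fit",
    "build_koff_profile",
    "fit_competition_models",
    "fit_kd",
    "fit_stoichiometry",
    "analyze_plate",
    "bic",
]

PLATE_COLUMNS = ("condition_id", "competitor_M", "replicate", "time_s", "polarization_mP")


class DegenerateDataError(ValueError):
    """Input data carry no usable signal (flat, empty, or rank-deficient)."""


def bic(rss: float, n: int, n_params: int) -> float:
    """Bayesian Information Criterion for a Gaussian least-squares fit,
    n*ln(RSS/n) + p*ln(n)."""
    if n <= 0 or rss < 0:
        raise ValueError("need n > 0 and RSS >= 0")
    rss = max(rss, np.finfo(float).tiny)
    return n * np.log(rss / n) + n_params * np.log(n)


@dataclass
class PlateTimeCourseSet:
    """Long-form plate-reader FPCD readings plus assay metadata.

    ``data`` columns: condition_id, competitor_M, replicate, time_s,
    polarization_mP.  Times are seconds since reaction initiation, so the
    first reading of each well sits at or after the dead time.
    """

    data: pd.DataFrame
    ligand: str = ""
    protein: str = ""
    temperature_C: float | None = None
    carrier: str | None = None
    dead_time_s: float = 90.0

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate data missing columns: {missing}")
        if not np.isfinite(self.data["polarization_mP"]).all():
            raise ValueError("polarization readings must be finite")
        for (c, r), grp in self.data.groupby(["competitor_M", "replicate"]):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times not strictly increasing for competitor {c}, replicate {r}"
                )

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["competitor_M"].unique())


@dataclass
class NormalizedDecay:
    """One well's normalized time course: fraction of initial complex vs time."""

    time_s: np.ndarray
    fraction: np.ndarray
    competitor_M: float
    replicate: object
    anchors: tuple[float, float]  # (P_min, P_max) used for normalization


@dataclass
class ExponentialFit:
    """One-phase exponential decay fit F(t) = A*exp(-k*t) + c."""

    k: float
    amplitude: float
    plateau: float
    rss: float
    n_points: int
    converged: bool
    partial: bool = False  # small amplitude or unresolved plateau
    competitor_M: float | None = None
    replicate: object = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.k * np.asarray(t)) + self.plateau


@dataclass
class KoffProfile:
    """Apparent off-rate versus competitor concentration."""

    competitor_M: np.ndarray
    koff_obs: np.ndarray
    sd: np.ndarray
    n_replicates: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ModelFit:
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    bic: float
    n: int


@dataclass
class CompetitionFitResult:
    """Classic vs direct-transfer regression of a k_off_obs profile."""

    classic: ModelFit
    direct_transfer: ModelFit
    selected: str  # "classic" | "direct_transfer" | "indeterminate"
    delta_bic: float  # BIC(direct_transfer) - BIC(classic)
    warnings: list[str] = field(default_factory=list)

    @property
    def k_neg1P(self) -> float:
        if self.selected == "direct_transfer":
            return self.direct_transfer.params["k_neg1P"]
        return self.classic.params["k_neg1P"]

    @property
    def k_thetaD(self) -> float:
        """Transfer constant; 0 by convention when classic is selected."""
        if self.selected == "direct_transfer":
            return self.direct_transfer.params["k_thetaD"]
        return 0.0


@dataclass
class KdFit:
    """Equilibrium binding-isotherm fit."""

    model: str  # standard | hill | quadratic
    K_d_M: float
    n_hill: float
    baseline_mP: float
    saturation_mP: float
    rss: float
    bic: float
    converged: bool
    ligand_limited: bool = False

    def predict(self, E: np.ndarray, ligand_M: float = 5e-9) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        if self.model == "quadratic":
            f = _quadratic_bound_fraction(E, ligand_M, self.K_d_M)
        else:
            En = np.power(E, self.n_hill)
            f = En / (En + self.K_d_M ** self.n_hill)
        return self.baseline_mP + (self.saturation_mP - self.baseline_mP) * f


@dataclass
class StoichiometryFit:
    """Two-segment (rising line / plateau) FP stoichiometry fit."""

    breakpoint_M: float
    ligand_M: float
    stoichiometry: float  # ligands per protein functional unit
    rss: float
    converged: bool


# ---------------------------------------------------------------------------
# normalization and per-well decay fitting


def normalize_polarization(
    plate: PlateTimeCourseSet,
    min_range_mP: float = 5.0,
    robust: bool = False,
    quantiles: tuple[float, float] = (0.01, 0.99),
    anchor_mode: str | None = None,
) -> list[NormalizedDecay]:
    """Map polarization onto fraction-of-initial-complex using the global
    signal range across all competitor concentrations.

    The highest-competitor wells decay to the free-ligand polarization floor
    while low-competitor wells stay near the bound ceiling, so the global
    extrema bracket the full bound<->free range.  Anchor policies:

    * ``extrema`` (default) — exact global min/max readings.
    * ``quantile`` (or ``robust=True``) — the given quantiles, resisting
      outlier wells.
    * ``plateau`` — ceiling from the mean of the lowest-competitor
      condition (whose complex persists) and floor from the mean of the
      final reads of the highest-competitor condition (fully decayed).
      Averaging makes the anchors insensitive to single-read noise, which
      otherwise rescales every fitted rate on the plate together.
    """
    pol = plate.data["polarization_mP"].to_numpy(dtype=float)
    if anchor_mode is None:
        anchor_mode = "quantile" if robust else "extrema"
    if anchor_mode == "quantile":
        p_min, p_max = np.quantile(pol, quantiles)
    elif anchor_mode == "plateau":
        concs = plate.concentrations
        lo_cond = plate.data[plate.data["competitor_M"] == concs[0]]
        hi_cond = plate.data[plate.data["competitor_M"] == concs[-1]]
        p_max = float(lo_cond["polarization_mP"].mean())
        t_tail = hi_cond["time_s"].quantile(0.9)
        p_min = float(
            hi_cond.loc[hi_cond["time_s"] >= t_tail, "polarization_mP"].mean()
        )
    elif anchor_mode == "extrema":
        p_min, p_max = float(pol.min()), float(pol.max())
    else:
        raise ValueError(f"unknown anchor mode {anchor_mode!r}")
    if p_max - p_min < min_range_mP:
        raise DegenerateDataError(
            f"polarization range {p_max - p_min:.3g} mP below minimum "
            f"{min_range_mP} mP; no competition signal to normalize"
        )
    out = []
    for (conc, rep), grp in plate.data.groupby(["competitor_M", "replicate"], sort=True):
        frac = (grp["polarization_mP"].to_numpy(dtype=float) - p_min) / (p_max - p_min)
        out.append(
            NormalizedDecay(
                time_s=grp["time_s"].to_numpy(dtype=float),
                fraction=frac,
                competitor_M=float(conc),
                replicate=rep,
                anchors=(p_min, p_max),
            )
        )
    return out


def fit_exponential_decay(
    decay: NormalizedDecay,
    n_starts: int = 8,
    partial_amplitude: float = 0.2,
) -> ExponentialFit:
    """Fit F(t) = A*exp(-k*t) + c by bounded least squares.

    Uses a deterministic grid of ``n_starts`` log-spaced rate
    initializations spanning the observation window; the lowest-RSS
    converged solution wins.  Fits with amplitude below
    ``partial_amplitude`` or with the plateau unresolved within the window
    are flagged partial rather than discarded.
    """
    t = np.asarray(decay.time_s, dtype=float)
    y = np.asarray(decay.fraction, dtype=float)
    if t.size < 5:
        raise ValueError(f"need >= 5 timepoints, got {t.size}")

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    k_grid = np.geomspace(0.01 / span, 100.0 / span, n_starts)

    def resid(p):
        k, a, c = p
        return a * np.exp(-k * t) + c - y

    best = None
    for k0 in k_grid:
        a0 = max(y.max() - y.min(), 1e-3)
        c0 = y.min()
        try:
            # the normalized fraction lives in [0, 1]; bounding the t = 0
            # amplitude near that range keeps the dead-time extrapolation of
            # fast chases from running away along the k-A likelihood ridge
            sol = least_squares(
                resid, [k0, a0, c0],
                bounds=([0.0, 0.0, -0.3], [np.inf, 1.3, 1.3]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        log.warning("exponential fit did not converge for competitor %s replicate %s",
                    decay.competitor_M, decay.replicate)
        return ExponentialFit(np.nan, np.nan, np.nan, np.inf, t.size, False,
                              competitor_M=decay.competitor_M, replicate=decay.replicate)
    k, a, c = best.x
    rss = float(2 * best.cost)
    # plateau unresolved if the window covers less than one decay time
    unresolved = k > 0 and (t[-1] - t[0]) * k < 1.0
    return ExponentialFit(
        k=float(k), amplitude=float(a), plateau=float(c),
        rss=rss, n_points=t.size, converged=True,
        partial=bool(a < partial_amplitude or unresolved),
        competitor_M=decay.competitor_M, replicate=decay.replicate,
    )


def koff_obs_from_fit(fit: ExponentialFit, convention: str = "initial_slope") -> float:
    """Apparent off-rate from a decay fit.

    ``initial_slope`` (default) returns k*A, the magnitude of dF/dt at t = 0
    of the normalized decay; ``rate`` returns the bare exponential rate k.
    The two agree when the decay is complete (A = 1, c = 0) and differ for
    partial-dissociation curves.
    """
    if not fit.converged:
        raise ValueError("cannot extract k_off_obs from a non-converged fit")
    if convention == "initial_slope":
        return fit.k * fit.amplitude
    if convention == "rate":
        return fit.k
    raise ValueError(f"unknown k_off_obs convention {convention!r}")


def build_koff_profile(
    fits: list[ExponentialFit],
    convention: str = "initial_slope",
) -> KoffProfile:
    """Aggregate per-well fits into mean +/- SD of k_off_obs per concentration.

    Non-converged wells are excluded with a logged warning.
    """
    rows: dict[float, list[float]] = {}
    for f in fits:
        if not f.converged:
            log.warning("excluding non-converged well (competitor %s, replicate %s)",
                        f.competitor_M, f.replicate)
            continue
        rows.setdefault(float(f.competitor_M), []).append(
            koff_obs_from_fit(f, convention)
        )
    if not rows:
        raise DegenerateDataError("no converged exponential fits to aggregate")
    conc = np.array(sorted(rows))
    koff = np.array([np.mean(rows[c]) for c in conc])
    sd = np.array([np.std(rows[c], ddof=1) if len(rows[c]) > 1 else 0.0 for c in conc])
    n = np.array([len(rows[c]) for c in conc])
    return KoffProfile(competitor_M=conc, koff_obs=koff, sd=sd, n_replicates=n,
                       meta={"convention": convention})


# ---------------------------------------------------------------------------
# competition regression with BIC model selection


def _classic_model(D, k_neg1, K_c):
    return k_neg1 * D / (D + K_c)


def _dt_model(D, k_neg1, K_c, k_theta):
    return _classic_model(D, k_neg1, K_c) + k_theta * D


def _wls(model, D, y, w, x0, bounds):
    def resid(p):
        return (model(D, *p) - y) * w

    sol = least_squares(resid, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    # weighted RSS: the same objective the parameters minimize, so the BIC
    # comparison between models is on a common likelihood scale
    rss = float(np.sum(((model(D, *sol.x) - y) * w) ** 2))
    # covariance from the weighted Jacobian (Gauss-Newton approximation)
    try:
        J = sol.jac
        dof = max(len(y) - len(sol.x), 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:  # pragma: no cover
        se = np.full(len(sol.x), np.nan)
    return sol.x, se, rss


def fit_competition_models(
    profile: KoffProfile,
    delta_bic_threshold: float = 2.0,
    min_concentrations: int = 4,
) -> CompetitionFitResult:
    """Regress k_off_obs(D) with the classic and direct-transfer models.

    classic:         koff = k_neg1P * D / (D + K_c)
    direct transfer: koff = k_neg1P * D / (D + K_c) + k_thetaD * D

    K_c is the capture constant — the competitor concentration at which
    capture of dissociated protein outcompetes rebinding of the trace
    labeled ligand.  Weighted by inverse replicate variance when >= 3
    replicates per point are available, else unweighted.  Models are
    compared by BIC; |dBIC| below ``delta_bic_threshold`` is reported
    indeterminate and defaults to the simpler classic model.
    """
    D = np.asarray(profile.competitor_M, dtype=float)
    y = np.asarray(profile.koff_obs, dtype=float)
    if D.size < min_concentrations:
        raise DegenerateDataError(
            f"need >= {min_concentrations} competitor concentrations, got {D.size}"
        )
    pos = D[D > 0]
    if pos.size >= 2 and pos.max() / pos.min() < 10:
        warnings.warn("competitor concentrations span < 10-fold; "
                      "model discrimination may be weak", stacklevel=2)

    if np.all(profile.n_replicates >= 3) and np.all(profile.sd > 0):
        w = 1.0 / profile.sd
        w = w / w.mean()
    else:
        w = np.ones_like(y)

    n = D.size
    kmax = max(y.max(), 1e-12)
    Dmid = np.median(pos) if pos.size else 1e-6

    # deterministic multi-start over capture-constant scales and transfer
    # slopes; the intercept start comes from the lowest capture-saturated
    # (positive-competitor) point, not from any zero-competitor point
    Kc_grid = Dmid * np.array([1e-3, 1e-2, 0.1, 1.0, 10.0])
    i_pos = int(np.argmax(D > 0)) if (D > 0).any() else 0
    y_low = max(y[i_pos], 1e-6 * kmax)
    slope_hi = max((y[-1] - y[i_pos]) / (D[-1] - D[i_pos] + 1e-300), 0.0)
    best_c = None
    for Kc0 in Kc_grid:
        fit = _wls(_classic_model, D, y, w, [kmax, Kc0],
                   ([0, 0], [np.inf, np.inf]))
        if best_c is None or fit[2] < best_c[2]:
            best_c = fit
    best_d = None
    for Kc0 in Kc_grid:
        for s0 in (1e-12, 0.5 * slope_hi + 1e-12, slope_hi + 1e-12):
            fit = _wls(_dt_model, D, y, w, [y_low, Kc0, s0],
                       ([0, 0, 0], [np.inf, np.inf, np.inf]))
            if best_d is None or fit[2] < best_d[2]:
                best_d = fit

    pc, sec, rss_c = best_c
    pd_, sed, rss_d = best_d
    fit_c = ModelFit(params={"k_neg1P": pc[0], "K_c": pc[1]},
                     stderr={"k_neg1P": sec[0], "K_c": sec[1]},
                     rss=rss_c, bic=bic(rss_c, n, 2), n=n)
    fit_d = ModelFit(params={"k_neg1P": pd_[0], "K_c": pd_[1], "k_thetaD": pd_[2]},
                     stderr={"k_neg1P": sed[0], "K_c": sed[1], "k_thetaD": sed[2]},
                     rss=rss_d, bic=bic(rss_d, n, 3), n=n)

    delta = fit_d.bic - fit_c.bic
    notes = []
    if abs(delta) < delta_bic_threshold:
        selected = "indeterminate"
        notes.append(
            f"|dBIC| = {abs(delta):.2f} < {delta_bic_threshold}; defaulting to classic"
        )
    elif delta < 0:
        selected = "direct_transfer"
    else:
        selected = "classic"
    if selected == "direct_transfer" and fit_d.params["k_thetaD"] <= 1e-12 * kmax / (D.max() + 1e-300):
        notes.append("k_thetaD at lower bound 0 in the selected transfer fit; "
                     "model ambiguity")
    return CompetitionFitResult(classic=fit_c, direct_transfer=fit_d,
                                selected=selected, delta_bic=delta, warnings=notes)


# ---------------------------------------------------------------------------
# equilibrium isotherm and stoichiometry fitting


def _quadratic_bound_fraction(E, L, Kd):
    """Exact 1:1 bound fraction of ligand with depletion (total protein E,
    total ligand L)."""
    E = np.asarray(E, dtype=float)
    b = E + L + Kd
    ep = (b - np.sqrt(np.clip(b * b - 4 * E * L, 0, None))) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(L > 0, ep / L, 0.0)


def fit_kd(
    protein_M: np.ndarray,
    polarization_mP: np.ndarray,
    model: str = "standard",
    ligand_M: float = 5e-9,
) -> KdFit:
    """Fit an equilibrium FP binding isotherm.

    ``standard``: hyperbolic 1:1 binding, P(E) = lo + (hi-lo)*E/(E+Kd)
    ``hill``:     P(E) = lo + (hi-lo)*E^n/(E^n+Kd^n)
    ``quadratic``: exact 1:1 binding polynomial with ligand depletion

    Flags ``ligand_limited`` when the fitted K_d falls below the lowest
    tested protein concentration (or, for the quadratic model, well below
    the ligand concentration), where the apparent K_d ceases to track the
    true affinity.
    """
    E = np.asarray(protein_M, dtype=float)
    y = np.asarray(polarization_mP, dtype=float)
    if E.size < 6:
        raise ValueError(f"need >= 6 protein concentrations, got {E.size}")
    if model not in ("standard", "hill", "quadratic"):
        raise ValueError(f"unknown isotherm model {model!r}")

    lo0, hi0 = float(y.min()), float(y.max())
    Epos = E[E > 0]
    Kd_grid = np.geomspace(Epos.min(), Epos.max(), 6) if Epos.size else [1e-9]

    def make_resid(mdl):
        def resid(p):
            if mdl == "standard":
                lo, hi, Kd = p
                f = E / (E + Kd)
            elif mdl == "hill":
                lo, hi, Kd, nH = p
                with np.errstate(divide="ignore", invalid="ignore"):
                    En = np.power(E, nH)
                    f = En / (En + Kd ** nH)
                f = np.nan_to_num(f)
            else:
                lo, hi, Kd = p
                f = _quadratic_bound_fraction(E, ligand_M, Kd)
            return lo + (hi - lo) * f - y
        return resid

    n_extra = 1 if model == "hill" else 0
    best = None
    for Kd0 in Kd_grid:
        x0 = [lo0, hi0, Kd0] + ([1.0] if n_extra else [])
        lb = [-np.inf, -np.inf, 1e-18] + ([0.05] if n_extra else [])
        ub = [np.inf, np.inf, np.inf] + ([10.0] if n_extra else [])
        try:
            sol = least_squares(make_resid(model), x0, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return KdFit(model, np.nan, np.nan, np.nan, np.nan, np.inf, np.inf, False)
    p = best.x
    rss = float(2 * best.cost)
    n_params = 3 + n_extra
    Kd = float(p[2])
    nH = float(p[3]) if n_extra else 1.0
    # an apparent K_d at/below the lowest tested concentration or below the
    # ligand concentration is curve-limited: the true K_d could be lower
    limited = (Epos.size > 0 and Kd <= Epos.min()) or Kd < ligand_M
    if limited:
        warnings.warn("fitted K_d below the resolvable range; the apparent K_d "
                      "may be ligand-limited (true K_d could be lower)", stacklevel=2)
    return KdFit(model=model, K_d_M=Kd, n_hill=nH,
                 baseline_mP=float(p[0]), saturation_mP=float(p[1]),
                 rss=rss, bic=bic(rss, E.size, n_params),
                 converged=bool(best.success), ligand_limited=limited)


def fit_stoichiometry(
    protein_M: np.ndarray,
    polarization_mP: np.ndarray,
    ligand_M: float,
) -> StoichiometryFit:
    """Two-segment breakpoint fit for FP stoichiometry titrations.

    With ligand far above K_d, polarization rises linearly with protein until
    every ligand is bound, then plateaus; the breakpoint protein
    concentration E_b gives stoichiometry = ligand / E_b (ligands per
    protein functional unit).
    """
    E = np.asarray(protein_M, dtype=float)
    y = np.asarray(polarization_mP, dtype=float)
    if E.size < 5:
        raise ValueError("need >= 5 titration points")

    def resid(p):
        lo, slope, brk = p
        return lo + slope * np.minimum(E, brk) - y

    span = E.max() - E.min()
    best = None
    for b0 in np.linspace(E.min() + 0.1 * span, E.max() - 0.1 * span, 8):
        s0 = (y.max() - y.min()) / max(b0, 1e-30)
        sol = least_squares(resid, [y.min(), s0, b0],
                            bounds=([-np.inf, 0, E.min()], [np.inf, np.inf, E.max()]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    brk = float(best.x[2])
    margin = 0.02 * span
    if brk <= E.min() + margin or brk >= E.max() - margin:
        raise DegenerateDataError(
            "no stoichiometry breakpoint detected inside the tested protein range"
        )
    return StoichiometryFit(breakpoint_M=brk, ligand_M=float(ligand_M),
                            stoichiometry=float(ligand_M) / brk,
                            rss=float(2 * best.cost), converged=bool(best.success))


# ---------------------------------------------------------------------------
# end-to-end convenience


def analyze_plate(
    plate: PlateTimeCourseSet,
    convention: str = "initial_slope",
    robust_normalization: bool = False,
    anchor_mode: str | None = None,
) -> tuple[list[ExponentialFit], KoffProfile, CompetitionFitResult]:
    """Run the full FPCD chain: normalize, fit decays, build the off-rate
    profile, and select classic vs direct transfer by BIC."""
    decays = normalize_polarization(plate, robust=robust_normalization,
                                    anchor_mode=anchor_mode)
    fits = [fit_exponential_decay(d) for d in decays]
    profile = build_koff_profile(fits, convention=convention)
    result = fit_competition_models(profile)
    return fits, profile, result
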
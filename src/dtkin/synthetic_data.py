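"""Seed-deterministic generators for every data type the pipelines consume.

The generators emulate the study's two instruments:

* a plate reader recording fluorescence polarization during competitive
  dissociation (and during equilibrium titrations), including the
  ~90 s initiation-measurement dead time before the first usable read; and
* a TIRF microscope recording per-particle intensity traces whose binding
  events terminate by dissociation, direct transfer, or photobleaching as
  competing exponentials, plus dual-color streams in which a transfer
  departure spawns an arrival in the other channel within the short
  ternary window.

Every generator takes an explicit seed and returns the ground truth next to
the data, so any downstream stage can be scored without re-derivation.
Defaults reflect the benchmark assay conditions: 5 nM labeled ligand,
100 nM protein, competitor chases up to 20 uM, 60/200 mP free/bound
polarization endpoints, and plate noise of 2.8 mP (2% of the signal range).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fp_pipeline import PlateTimeCourseSet
from .kinetics_core import (
    RateConstants,
    ReactionTotals,
    SpeciesState,
    equilibrium_state,
    simulate_scheme,
)
from .sm_pipeline import BindingEvent, DwellTimeSet, IntensityTrace

__all__ = [
    "FpPlateDesign",
    "IsothermDesign",
    "SmDesign",
    "ParameterPreset",
    "preset_registry",
    "get_preset",
    "generate_fpcd_dataset",
    "generate_isotherm",
    "generate_sm_dataset",
]

# Default chase series. A zero-competitor well anchors the bound-state
# polarization ceiling (its complex never decays net of rebinding); the
# lowest chase concentration sits well above the protein concentration so
# free protein is sequestered quickly and the decay reports the apparent
# off-rate; the top concentration is capped so the fastest chase is still
# resolvable after the ~90 s initiation-measurement dead time.
DEFAULT_COMPETITOR_CONCS_M = (
    0.0, 3e-7, 6e-7, 1e-6, 2e-6, 3e-6, 4.5e-6, 6e-6,
)


@dataclass
class ParameterPreset:
    """Named kinetic parameter set for one protein–ligand interaction."""

    name: str
    k_neg1: float  # 1/s
    k_theta: float  # 1/(M s)
    K_d_app_M: float
    temperature_C: float
    provenance: str = ""

    def rate_constants(self) -> RateConstants:
        """Self-competition rate constants (ligand and competitor identical).

        The association constant is fixed by k1 = k_neg1 / K_d, since only
        the dissociation and transfer constants are measured directly.
        """
        return RateConstants.self_competition(
            k1=self.k_neg1 / self.K_d_app_M,
            k_neg1=self.k_neg1,
            k_theta=self.k_theta,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ParameterPreset":
        return cls(**json.loads(s))


_PRESETS = [
    ParameterPreset("hnRNPU_4C", 6.4e-4, 39.0, 15e-9, 4.0,
                    "hnRNP-U + G-quadruplex RNA self-competition, 4 C "
                    "(K_d from the 25 C titration)"),
    ParameterPreset("TREX1_ssDNA_25C", 7.0e-3, 1500.0, 8.9e-9, 25.0,
                    "TREX1 + ssDNA 5-mer self-competition, 25 C"),
    ParameterPreset("TREX1_ssDNA_4C", 6.8e-3, 700.0, 8.9e-9, 4.0,
                    "TREX1 + ssDNA 5-mer self-competition, 4 C "
                    "(K_d from the 25 C titration)"),
    ParameterPreset("TREX1_dsDNA_25C", 1.9e-2, 0.0, 30e-9, 25.0,
                    "TREX1 + 60-bp dsDNA ligand chased with ssDNA 5-mer, 25 C; "
                    "classic competition (no detectable transfer)"),
    ParameterPreset("FBF2_25C", 4.4e-3, 140.0, 50e-9, 25.0,
                    "FBF-2 + PUF-element ssRNA self-competition, 25 C"),
    ParameterPreset("MS2CP_25C", 1.4e-3, 89.0, 2.9e-9, 25.0,
                    "MS2 coat protein + RNA hairpin competition, 25 C "
                    "(apparent K_d likely ligand-limited)"),
    ParameterPreset("Streptavidin_25C", 1.3e-5, 0.0, 2.5e-9, 25.0,
                    "streptavidin + biotin, 25 C; classic competition control "
                    "(apparent K_d likely ligand-limited)"),
    ParameterPreset("TREX1_SM", 4.0e-2, 9800.0, 8.9e-9, 25.0,
                    "TREX1 + ssDNA 5-mer from single-molecule TIRF residence "
                    "times (different buffer from the plate assay)"),
]


def preset_registry() -> list[ParameterPreset]:
    """All bundled parameter presets."""
    return list(_PRESETS)


def get_preset(name: str) -> ParameterPreset:
    for p in _PRESETS:
        if p.name == name:
            return p
    raise KeyError(f"no preset named {name!r}; known: {[p.name for p in _PRESETS]}")


# ---------------------------------------------------------------------------
# plate-reader FPCD data


@dataclass
class FpPlateDesign:
    """Layout and noise model of a synthetic FPCD plate."""

    competitor_concs_M: tuple[float, ...] = DEFAULT_COMPETITOR_CONCS_M
    replicates: int = 4
    read_interval_s: float = 10.0
    duration_s: float = 1800.0
    dead_time_s: float = 90.0
    E_total_M: float = 100e-9
    P_total_M: float = 5e-9
    polarization_free_mP: float = 60.0
    polarization_bound_mP: float = 200.0
    noise_sd_mP: float = 2.8
    carrier: str | None = None  # named non-binding carrier species, or None
    carrier_total_M: float | None = None  # constant total polynucleotide

    def __post_init__(self) -> None:
        if self.duration_s <= self.dead_time_s:
            raise ValueError("duration must exceed the dead time")
        if self.polarization_free_mP == self.polarization_bound_mP:
            raise ValueError("polarization endpoints must be distinct")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.carrier is not None:
            top = self.carrier_total_M or max(self.competitor_concs_M)
            if top < max(self.competitor_concs_M):
                raise ValueError("carrier total below highest competitor conc")


def generate_fpcd_dataset(
    preset: ParameterPreset,
    design: FpPlateDesign | None = None,
    seed: int = 0,
) -> tuple[PlateTimeCourseSet, dict]:
    """Simulate an FPCD plate from a kinetic preset.

    The labeled complex is pre-equilibrated without competitor, competitor
    is added at t = 0, and the simplified scheme is integrated for each
    concentration.  The bound fraction of labeled ligand maps linearly onto
    polarization between the free and bound endpoints; i.i.d. Gaussian
    noise is added per replicate and reads before the dead time are
    dropped.  When a carrier species is configured it is recorded in the
    metadata only — it binds nothing and changes no rates; its role is to
    keep total polynucleotide constant across the dilution series.

    Returns the plate plus a ground-truth dict (generating rates, noiseless
    bound fractions, seed).
    """
    design = design or FpPlateDesign()
    rng = np.random.default_rng(seed)
    rates = preset.rate_constants()

    eq0 = equilibrium_state(
        rates, ReactionTotals(design.E_total_M, design.P_total_M, 0.0)
    )
    times = np.arange(0.0, design.duration_s + 1e-9, design.read_interval_s)
    kept = times >= design.dead_time_s
    if not kept.any():
        raise ValueError("no reads survive the dead time")

    p_span = design.polarization_bound_mP - design.polarization_free_mP
    rows = []
    truth_fractions = {}
    for D in design.competitor_concs_M:
        totals = ReactionTotals(design.E_total_M, design.P_total_M, D)
        y0 = SpeciesState(E=eq0.E, P=eq0.P, D=D, EP=eq0.EP, ED=0.0)
        tc = simulate_scheme(rates, totals, times, y0=y0)
        frac = tc.bound_fraction_P()
        truth_fractions[D] = frac[kept].tolist()
        clean = design.polarization_free_mP + p_span * frac
        for rep in range(1, design.replicates + 1):
            noisy = clean + rng.normal(0.0, design.noise_sd_mP, size=clean.size)
            for t, p in zip(times[kept], noisy[kept]):
                rows.append({
                    "condition_id": f"{preset.name}_D{D:g}",
                    "competitor_M": D,
                    "replicate": rep,
                    "time_s": t,
                    "polarization_mP": p,
                })

    # warn if the chase never approaches the free-ligand floor, which would
    # break the global-range normalization assumption
    top_frac = np.asarray(truth_fractions[max(design.competitor_concs_M)])
    if top_frac[-1] > 0.1:
        import warnings
        warnings.warn(
            "saturating-competitor condition does not reach the free-ligand "
            "plateau within the simulated duration; normalization anchors "
            "will be biased", stacklevel=2,
        )

    plate = PlateTimeCourseSet(
        data=pd.DataFrame(rows),
        ligand=preset.name,
        protein=preset.name.split("_")[0],
        temperature_C=preset.temperature_C,
        carrier=design.carrier,
        dead_time_s=design.dead_time_s,
    )
    truth = {
        "preset": preset.name,
        "k_neg1": preset.k_neg1,
        "k_theta": preset.k_theta,
        "K_d_app_M": preset.K_d_app_M,
        "bound_fraction": truth_fractions,
        "seed": seed,
        "design": asdict(design),
    }
    return plate, truth


# ---------------------------------------------------------------------------
# equilibrium isotherms


@dataclass
class IsothermDesign:
    """Protein titration layout for equilibrium binding curves."""

    protein_concs_M: tuple[float, ...] = tuple(np.geomspace(1e-10, 2e-6, 12))
    replicates: int = 2  # duplicate wells per concentration
    ligand_M: float = 5e-9
    polarization_free_mP: float = 60.0
    polarization_bound_mP: float = 200.0
    noise_sd_mP: float = 2.8
    depletion: bool = False  # exact binding polynomial (ligand-limited regime)


def generate_isotherm(
    K_d: float,
    n_H: float = 1.0,
    design: IsothermDesign | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a noisy FP binding isotherm.

    Bound fraction follows the Hill form E^n/(E^n + K_d^n); with n_H = 1
    this is the standard hyperbola.  In depletion mode the exact 1:1
    binding polynomial is used instead, producing the ligand-limited curves
    whose apparent midpoint sits near half the ligand concentration rather
    than at K_d.
    """
    if K_d <= 0 or n_H <= 0:
        raise ValueError("K_d and n_H must be > 0")
    design = design or IsothermDesign()
    rng = np.random.default_rng(seed)
    E1 = np.asarray(design.protein_concs_M, dtype=float)
    if design.depletion:
        from .fp_pipeline import _quadratic_bound_fraction
        frac = _quadratic_bound_fraction(E1, design.ligand_M, K_d)
    else:
        En = np.power(E1, n_H)
        frac = En / (En + K_d ** n_H)
    span = design.polarization_bound_mP - design.polarization_free_mP
    E = np.tile(E1, design.replicates)
    pol = design.polarization_free_mP + span * np.tile(frac, design.replicates) \
        + rng.normal(0.0, design.noise_sd_mP, size=E.size)
    df = pd.DataFrame({"protein_M": E, "polarization_mP": pol})
    truth = {
        "K_d_M": K_d, "n_H": n_H, "depletion": design.depletion,
        "bound_fraction": frac.tolist(), "seed": seed, "design": asdict(design),
    }
    return df, truth


# ---------------------------------------------------------------------------
# single-molecule data


@dataclass
class SmDesign:
    """Single-molecule acquisition and kinetic ground truth.

    Dwell terminations compete: dissociation (k_neg1), transfer
    (k_theta * competitor), and photobleaching (k_b), so observed dwells
    are exponential with the summed rate.  In two-color mode a fraction of
    departures (``transfer_probability``) are ligand hand-offs that spawn
    an arrival in the other channel within the ternary window.
    """

    n_events: int = 500
    n_traces: int = 100
    frame_interval_s: float = 0.2
    trace_frames: int = 600
    k_neg1: float = 4.0e-2
    k_theta: float = 9800.0
    competitor_M: float = 0.0
    k_b: float = 0.0
    snr: float = 5.0
    t_min_s: float = 0.4  # minimum resolvable dwell (2 frames at 0.2 s)
    arrival_rate_s: float = 0.02  # per-particle binding arrivals
    transfer_probability: float = 0.0
    ternary_window_s: float = 0.15

    def __post_init__(self) -> None:
        if min(self.k_neg1, self.k_theta, self.competitor_M, self.k_b) < 0:
            raise ValueError("rates and concentrations must be >= 0")
        if self.snr <= 0:
            raise ValueError("SNR must be > 0")
        if not 0 <= self.transfer_probability <= 1:
            raise ValueError("transfer probability must be in [0, 1]")

    @property
    def total_rate(self) -> float:
        return self.k_neg1 + self.k_theta * self.competitor_M + self.k_b


def _draw_dwells(design: SmDesign, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    k_tot = design.total_rate
    if k_tot <= 0:
        raise ValueError("total termination rate must be > 0")
    # left-truncated sampling: only dwells exceeding t_min are recorded, and
    # by memorylessness the excess over t_min has the same exponential law
    durations = design.t_min_s + rng.exponential(1.0 / k_tot, size=design.n_events)
    p = np.array([design.k_neg1, design.k_theta * design.competitor_M, design.k_b])
    p = p / p.sum()
    causes = rng.choice(["dissociation", "transfer", "bleach"],
                        size=design.n_events, p=p)
    return durations, causes.tolist()


def generate_sm_dataset(
    design: SmDesign | None = None,
    seed: int = 0,
    mode: str = "dwells",
) -> dict:
    """Generate single-molecule data in one of three modes.

    ``dwells``    — a :class:`DwellTimeSet` of residence times.
    ``traces``    — two-level intensity traces with Gaussian noise and the
                    true event list per trace.
    ``two_color`` — paired red/green event streams per particle where a
                    fraction of departures are transfers.

    Always returns a dict with a ``truth`` entry carrying the generating
    parameters, per-event termination causes, and bookkeeping counts.
    """
    design = design or SmDesign()
    rng = np.random.default_rng(seed)
    truth: dict = {"seed": seed, "mode": mode, "design": asdict(design),
                   "total_rate": design.total_rate}

    if mode == "dwells":
        durations, causes = _draw_dwells(design, rng)
        dwells = DwellTimeSet(durations_s=durations,
                              competitor_M=design.competitor_M,
                              t_min_s=design.t_min_s)
        counts = {c: causes.count(c) for c in ("dissociation", "transfer", "bleach")}
        counts["censored"] = 0
        truth.update({"causes": causes, "counts": counts,
                      "n_total": design.n_events})
        return {"dwells": dwells, "truth": truth}

    if mode == "traces":
        traces, event_lists = [], []
        dt = design.frame_interval_s
        counts = {"dissociation": 0, "transfer": 0, "bleach": 0, "censored": 0}
        p_cause = np.array([design.k_neg1,
                            design.k_theta * design.competitor_M,
                            design.k_b])
        p_cause = p_cause / p_cause.sum()
        for pid in range(design.n_traces):
            frames = design.trace_frames
            signal = np.zeros(frames)
            events = []
            t = rng.exponential(1.0 / design.arrival_rate_s)
            while t < frames * dt:
                dwell = rng.exponential(1.0 / design.total_rate)
                start = int(np.round(t / dt))
                end = int(np.round((t + dwell) / dt))
                if end > frames:
                    if frames - start >= 2:
                        events.append(BindingEvent(start, frames, dt,
                                                   particle_id=pid, censored=True))
                        counts["censored"] += 1
                        signal[start:frames] = 1.0
                    break
                if end - start >= 2:
                    cause = rng.choice(["dissociation", "transfer", "bleach"],
                                       p=p_cause)
                    counts[cause] += 1
                    events.append(BindingEvent(start, end, dt, particle_id=pid))
                    signal[start:end] = 1.0
                t = t + dwell + rng.exponential(1.0 / design.arrival_rate_s)
            noisy = signal + rng.normal(0.0, 1.0 / design.snr, size=frames)
            traces.append(IntensityTrace(noisy, dt, particle_id=pid))
            event_lists.append(events)
        truth.update({"events": event_lists, "counts": counts})
        return {"traces": traces, "truth": truth}

    if mode == "two_color":
        events_red: list[BindingEvent] = []
        events_green: list[BindingEvent] = []
        by_channel = {"red": events_red, "green": events_green}
        dt = design.frame_interval_s
        horizon = design.trace_frames * dt
        n_transfers = 0
        n_departures = 0
        for pid in range(design.n_traces):
            occupied_until = {"red": 0.0, "green": 0.0}
            t = rng.exponential(1.0 / design.arrival_rate_s)
            channel = "red" if rng.random() < 0.5 else "green"
            while t < horizon:
                if t < occupied_until[channel]:
                    t = occupied_until[channel]
                dwell = rng.exponential(1.0 / design.total_rate)
                start, end = t, t + dwell
                sf, ef = int(np.round(start / dt)), int(np.round(end / dt))
                if ef >= design.trace_frames:
                    ef = design.trace_frames
                    if ef - sf >= 2:
                        by_channel[channel].append(BindingEvent(
                            sf, ef, dt, channel, pid, censored=True))
                    break
                if ef - sf >= 2:
                    by_channel[channel].append(BindingEvent(sf, ef, dt, channel, pid))
                    n_departures += 1
                    occupied_until[channel] = end
                    other = "green" if channel == "red" else "red"
                    if (rng.random() < design.transfer_probability
                            and end >= occupied_until[other]):
                        # hand-off: arrival in the other channel inside the
                        # ternary window
                        n_transfers += 1
                        t = end + rng.uniform(0.0, 0.5 * design.ternary_window_s)
                        channel = other
                        continue
                t = end + rng.exponential(1.0 / design.arrival_rate_s)
                channel = "red" if rng.random() < 0.5 else "green"
        truth.update({
            "n_departures": n_departures,
            "n_transfers": n_transfers,
            "transfer_fraction_pct": (100.0 * n_transfers / n_departures
                                      if n_departures else 0.0),
        })
        return {"events_red": events_red, "events_green": events_green,
                "truth": truth}

    raise ValueError(f"unknown mode {mode!r}; use dwells|traces|two_color")
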
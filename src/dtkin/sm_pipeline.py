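"""Single-molecule TIRF residence-time analysis.

Works from per-particle intensity traces (or pre-extracted dwell lists):
detects binding events by hysteresis thresholding, compiles residence
times, fits a left-truncated exponential by maximum likelihood, corrects
the apparent off-rate for photobleaching as a competing exponential, and —
for dual-color experiments — classifies direct-transfer events where one
ligand departs as another arrives at the same particle within a short
ternary window.

The apparent off-rate at competitor concentration D follows
koff_obs(D) = k_neg1 + k_theta * D, so a zero-competitor condition gives
k_neg1 and a chase condition gives k_theta by finite difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IntensityTrace",
    "BindingEvent",
    "DwellTimeSet",
    "SmRateEstimate",
    "TransferEvent",
    "detect_events",
    "fit_dwell_exponential",
    "estimate_rate_constants",
    "photobleach_correct",
    "detect_transfer_events",
    "transfer_event_fraction",
]


@dataclass
class IntensityTrace:
    """Per-frame intensity of one diffraction-limited particle."""

    intensity: np.ndarray
    frame_interval_s: float
    channel: str = "red"
    particle_id: object = 0
    acquisition: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be > 0")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class BindingEvent:
    """Half-open frame span [start, end) of one binding event (0-based)."""

    start: int
    end: int
    frame_interval_s: float
    channel: str = "red"
    particle_id: object = 0
    censored: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) * self.frame_interval_s

    @property
    def start_s(self) -> float:
        return self.start * self.frame_interval_s

    @property
    def end_s(self) -> float:
        return self.end * self.frame_interval_s


@dataclass
class DwellTimeSet:
    """Residence times under one reaction condition."""

    durations_s: np.ndarray
    competitor_M: float = 0.0
    t_min_s: float = 0.0
    censored: np.ndarray | None = None  # bool mask aligned to durations

    def __post_init__(self) -> None:
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.durations_s.shape, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.durations_s < self.t_min_s - 1e-12):
            raise ValueError("all dwells must be >= the minimum resolvable dwell")

    @property
    def n(self) -> int:
        return int(self.durations_s.size)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


@dataclass
class SmRateEstimate:
    """Rate constants derived from +/- competitor dwell analysis."""

    koff_obs: dict[float, float]  # condition (M) -> apparent rate (1/s)
    koff_sd: dict[float, float] = field(default_factory=dict)
    k_b: float | None = None
    k_neg1: float | None = None
    k_theta: float | None = None
    bleach_fraction: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TransferEvent:
    """A departure in one channel paired with an arrival in the other."""

    particle_id: object
    departing_channel: str
    departing_frame: int
    arriving_channel: str
    arriving_frame: int
    gap_s: float  # arrival start minus departure end; <= 0 means overlap


def detect_events(
    trace: IntensityTrace,
    high_threshold: float | None = None,
    low_threshold: float | None = None,
    n_mad_high: float = 5.0,
    n_mad_low: float = 2.5,
    min_dwell_frames: int = 2,
) -> list[BindingEvent]:
    """Segment a trace into binding events by hysteresis thresholding.

    The bound state is entered when intensity rises above the high threshold
    and left when it falls below the low one, which suppresses chatter from
    noise straddling a single cutoff.  Thresholds default to
    median + n*MAD of the trace.  Events shorter than ``min_dwell_frames``
    are discarded as unresolvable; an event still bound at the final frame
    is flagged censored.
    """
    x = trace.intensity
    if x.size < 10:
        raise ValueError("trace too short for event detection (< 10 frames)")
    if high_threshold is None or low_threshold is None:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        sigma = 1.4826 * mad if mad > 0 else float(np.std(x)) or 1.0
        high_threshold = med + n_mad_high * sigma if high_threshold is None else high_threshold
        low_threshold = med + n_mad_low * sigma if low_threshold is None else low_threshold
    if low_threshold >= high_threshold:
        raise ValueError("low threshold must be below high threshold")

    events: list[BindingEvent] = []
    bound = False
    start = 0
    for i, v in enumerate(x):
        if not bound and v >= high_threshold:
            bound = True
            start = i
        elif bound and v < low_threshold:
            if i - start >= min_dwell_frames:
                events.append(BindingEvent(start, i, trace.frame_interval_s,
                                           trace.channel, trace.particle_id))
            bound = False
    if bound and x.size - start >= min_dwell_frames:
        events.append(BindingEvent(start, x.size, trace.frame_interval_s,
                                   trace.channel, trace.particle_id, censored=True))
    return events


def fit_dwell_exponential(
    dwells: DwellTimeSet,
    min_events: int = 20,
    include_censored: bool = False,
) -> float:
    """Maximum-likelihood rate of a left-truncated exponential dwell model.

    Only dwells longer than the minimum resolvable time t_min are observed,
    and by memorylessness the excess t - t_min is exponential with the same
    rate, so the uncensored MLE is the closed form n / sum(t_i - t_min).
    With ``include_censored`` the right-censored dwells contribute survival
    terms: rate = n_uncensored / sum over all events of (t_i - t_min).
    """
    if include_censored:
        use = np.ones(dwells.n, dtype=bool)
    else:
        use = ~dwells.censored
    t = dwells.durations_s[use]
    cens = dwells.censored[use]
    n_unc = int((~cens).sum())
    if n_unc < min_events:
        raise ValueError(
            f"need >= {min_events} uncensored dwell times, got {n_unc}"
        )
    excess = float(np.sum(t - dwells.t_min_s))
    if excess <= 0:
        raise ValueError("all dwells at the minimum resolvable time; "
                         "rate is unidentifiable (degenerate data)")
    return n_unc / excess


def estimate_rate_constants(
    koff_zero: float,
    koff_D: float,
    D: float,
) -> tuple[float, float]:
    """Intrinsic dissociation and transfer constants from two conditions.

    koff_obs(D) = k_neg1 + k_theta * D, so k_neg1 is the zero-competitor
    apparent rate and k_theta the excess rate per molar competitor.  A
    negative slope (within noise) is clamped to 0 with a warning.
    """
    if D <= 0:
        raise ValueError("competitor concentration must be > 0")
    if koff_zero < 0 or koff_D < 0:
        raise ValueError("apparent rates must be >= 0")
    k_neg1 = koff_zero
    k_theta = (koff_D - koff_zero) / D
    if k_theta < 0:
        warnings.warn(
            f"apparent rate decreased with competitor (k_theta = {k_theta:.3g}); "
            "clamping to 0", stacklevel=2,
        )
        k_theta = 0.0
    return k_neg1, k_theta


def photobleach_correct(estimate: SmRateEstimate, k_b: float) -> SmRateEstimate:
    """Subtract the photobleaching rate from every apparent off-rate.

    Bleaching terminates fluorescence as a competing exponential, so the
    observed rate is the sum of the true departure rate and k_b.  Reports
    the fraction of apparent dissociations attributable to bleaching per
    condition, and re-derives k_neg1/k_theta from the corrected rates when
    a zero-competitor condition is present.
    """
    if k_b < 0:
        raise ValueError("photobleach rate must be >= 0")
    for cond, koff in estimate.koff_obs.items():
        if k_b >= koff:
            raise ValueError(
                f"photobleach rate {k_b} >= apparent rate {koff} at "
                f"competitor {cond}; bleaching cannot exceed the apparent rate"
            )
    corrected = {c: k - k_b for c, k in estimate.koff_obs.items()}
    frac = {c: k_b / k for c, k in estimate.koff_obs.items()}
    out = replace(estimate, koff_obs=corrected, k_b=k_b, bleach_fraction=frac)
    if 0.0 in corrected and len(corrected) > 1:
        conds = [c for c in corrected if c > 0]
        c = max(conds)
        out.k_neg1, out.k_theta = estimate_rate_constants(
            corrected[0.0], corrected[c], c
        )
    return out


def detect_transfer_events(
    events_red: list[BindingEvent],
    events_green: list[BindingEvent],
    window_s: float = 0.15,
) -> list[TransferEvent]:
    """Pair departures in one channel with arrivals in the other.

    A transfer is scored when, at the same (pre-colocalized) particle, one
    channel's event ends within ``window_s`` of the other channel's event
    beginning — the signature of hand-off through a ternary intermediate
    too short-lived to resolve.  Sustained double occupancy (overlap longer
    than the window) is not a transfer.  Symmetric under channel swap.
    """
    if window_s <= 0:
        raise ValueError("ternary window must be > 0")
    transfers: list[TransferEvent] = []
    for departing, arriving in ((events_red, events_green),
                                (events_green, events_red)):
        for dep in departing:
            if dep.censored:
                continue  # no departure observed
            for arr in arriving:
                if arr.particle_id != dep.particle_id:
                    continue
                gap = arr.start_s - dep.end_s
                if abs(gap) <= window_s:
                    transfers.append(TransferEvent(
                        particle_id=dep.particle_id,
                        departing_channel=dep.channel,
                        departing_frame=dep.end,
                        arriving_channel=arr.channel,
                        arriving_frame=arr.start,
                        gap_s=gap,
                    ))
    transfers.sort(key=lambda tr: (str(tr.particle_id), tr.departing_frame))
    return transfers


def transfer_event_fraction(transfers: int, total_binding_events: int) -> float:
    """Percentage of binding events that terminate in a direct transfer."""
    if total_binding_events <= 0:
        raise ValueError("total binding events must be > 0")
    if transfers < 0 or transfers > total_binding_events:
        raise ValueError("transfer count must lie in [0, total]")
    return 100.0 * transfers / total_binding_events
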
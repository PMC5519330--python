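"""Stimulation protocols: Poisson trains, paired pulses, parabolic bursts.

All protocols are trains of identical brief (1 ms) current pulses
applied to the first compartment.  The default amplitude is 4 nA: with
the model's input resistance (~16 MOhm at the sealed end) and 8 ms
membrane time constant, a 1 ms pulse depolarizes the stimulated end by
only ~1.2 mV/nA, so single-pulse rheobase is 2-3.5 nA across model
variants and operating points.  4 nA sits just above rheobase, the
regime of a threshold-level experimental drive: a lone pulse always
fires, while pulses landing in the deep relative-refractory zone
(intervals shorter than ~10 ms) fail to initiate instead of firing
grossly slowed spikes.  The amplitude only launches the spike --
conduction delay is measured between two sites far from the stimulated
end and is insensitive to it.

A 2 ms minimum inter-onset interval (pulse width plus a 1 ms guard)
keeps pulses from overlapping; at the mean rates used here (<= 19 Hz)
redrawing sub-floor Poisson intervals perturbs the interval
distribution negligibly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusTrain",
    "poisson_train",
    "paired_pulse_set",
    "default_isi_grid",
    "parabolic_burst_train",
    "MIN_INTERVAL_MS",
    "DEFAULT_AMPLITUDE_NA",
]

MIN_INTERVAL_MS = 2.0

#: default pulse amplitude (nA); see module docstring
DEFAULT_AMPLITUDE_NA = 4.0


@dataclass(frozen=True)
class StimulusTrain:
    """Timed current pulses: strictly increasing onsets, fixed shape."""

    onsets_ms: np.ndarray
    amplitude_na: float = DEFAULT_AMPLITUDE_NA
    width_ms: float = 1.0
    label: str = "custom"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        on = np.asarray(self.onsets_ms, dtype=float)
        object.__setattr__(self, "onsets_ms", on)
        if on.size and (np.any(on < 0) or np.any(np.diff(on) < MIN_INTERVAL_MS - 1e-9)):
            raise ValueError(
                f"onsets must be >= 0 with intervals >= {MIN_INTERVAL_MS} ms")

    def __len__(self) -> int:
        return int(self.onsets_ms.size)

    @property
    def duration_ms(self) -> float:
        return float(self.onsets_ms[-1] + self.width_ms) if len(self) else 0.0

    def shifted(self, offset_ms: float) -> "StimulusTrain":
        return StimulusTrain(self.onsets_ms + offset_ms, self.amplitude_na,
                             self.width_ms, self.label, self.seed, dict(self.meta))

    # -- serialization (two-column table with a '#' header block) ----------
    def to_csv(self, path) -> None:
        header = [f"# label: {self.label}", f"# seed: {self.seed}",
                  f"# width_ms: {self.width_ms}"]
        header += [f"# {k}: {v}" for k, v in sorted(self.meta.items())]
        df = pd.DataFrame({"onset_ms": self.onsets_ms,
                           "amplitude_nA": self.amplitude_na})
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, index=False)  # default float repr round-trips exactly

    @classmethod
    def from_csv(cls, path) -> "StimulusTrain":
        meta: dict = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                else:
                    lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)), float_precision="round_trip")
        seed = meta.pop("seed", "None")
        extra = {k: v for k, v in meta.items()
                 if k not in ("label", "width_ms")}
        amp = float(df["amplitude_nA"].iloc[0]) if len(df) else DEFAULT_AMPLITUDE_NA
        return cls(df["onset_ms"].to_numpy(), amplitude_na=amp,
                   width_ms=float(meta.get("width_ms", 1.0)),
                   label=meta.get("label", "custom"),
                   seed=None if seed == "None" else int(seed), meta=extra)


def poisson_train(mean_rate_hz: float, duration_s: float,
                  seed: int | None = None) -> StimulusTrain:
    """Homogeneous Poisson pulse train of a given mean rate and duration.

    Exponential inter-onset intervals; draws below the 2 ms floor are
    redrawn.  Raises if the floor would distort the mean rate by > 5 %
    (i.e. for rates approaching 1/(2 ms)).
    """
    if mean_rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate and duration must be positive")
    # with redrawing, realized mean interval is floor + 1/rate restricted to
    # tail: E[T | T >= floor] = floor + 1/rate for an exponential
    nominal = 1e3 / mean_rate_hz
    if MIN_INTERVAL_MS / nominal > 0.05:
        raise ValueError(
            f"rate {mean_rate_hz} Hz too high: {MIN_INTERVAL_MS} ms refractory floor "
            "would distort the mean rate by more than 5%")
    rng = np.random.default_rng(seed)
    duration_ms = duration_s * 1e3
    # draw in blocks; memorylessness makes redrawing equivalent to rejection
    onsets = []
    t = 0.0
    n_guess = int(mean_rate_hz * duration_s * 1.3) + 64
    while True:
        draws = rng.exponential(nominal, size=n_guess)
        for d in draws:
            if d < MIN_INTERVAL_MS:
                continue
            t += d
            if t > duration_ms:
                return StimulusTrain(np.asarray(onsets), label="poisson", seed=seed,
                                     meta={"mean_rate_hz": mean_rate_hz,
                                           "duration_s": duration_s})
            onsets.append(t)
        n_guess = max(64, n_guess // 4)


def paired_pulse_set(isis_ms) -> list[StimulusTrain]:
    """One conditioning+test two-pulse train per inter-stimulus interval.

    Each train starts at time 0; every trial is meant to run from an
    identical initial (rest) state.
    """
    trains = []
    for isi in np.asarray(isis_ms, dtype=float):
        if isi < MIN_INTERVAL_MS:
            raise ValueError(f"ISI {isi} ms below the {MIN_INTERVAL_MS} ms floor")
        trains.append(StimulusTrain(np.array([0.0, isi]), label="paired",
                                    meta={"isi_ms": float(isi)}))
    return trains


def default_isi_grid(n: int = 30, lo_ms: float = 10.0,
                     hi_ms: float = 10_000.0) -> np.ndarray:
    """Log-spaced recovery-cycle ISI grid, 10 ms to 10 s by default."""
    return np.geomspace(lo_ms, hi_ms, n)


def parabolic_burst_train(n_bursts: int = 300, period_s: float = 1.0,
                          n_spikes: int = 19, f_start_hz: float = 32.0,
                          f_peak_hz: float = 63.0) -> StimulusTrain:
    """Rhythmic bursting: parabolic instantaneous frequency within bursts.

    Each burst holds ``n_spikes`` pulses whose instantaneous frequency
    rises from ``f_start`` to ``f_peak`` at mid-burst and falls back,
    following an inverted parabola over the interval index; bursts repeat
    with the given period (emulates the pyloric dilator rhythm).
    """
    if n_spikes % 2 == 0:
        raise ValueError("n_spikes must be odd so the peak lands mid-burst")
    if n_spikes < 3 or n_bursts < 1:
        raise ValueError("need at least 3 spikes per burst and 1 burst")
    n_int = n_spikes - 1
    k = np.arange(n_int)
    k_mid = (n_int - 1) / 2.0
    shape = 1.0 - ((k - k_mid) / k_mid) ** 2
    # an odd spike count means an even interval count: normalize the
    # parabola so the two central intervals sit exactly at f_peak
    f = f_start_hz + (f_peak_hz - f_start_hz) * shape / shape.max()
    isis_ms = 1e3 / f
    burst_dur = float(np.sum(isis_ms))
    period_ms = period_s * 1e3
    if period_ms <= burst_dur:
        raise ValueError(
            f"burst period {period_ms:g} ms shorter than burst duration {burst_dur:g} ms")
    within = np.concatenate([[0.0], np.cumsum(isis_ms)])
    onsets = (period_ms * np.arange(n_bursts)[:, None] + within[None, :]).ravel()
    return StimulusTrain(onsets, label="burst",
                         meta={"n_bursts": n_bursts, "period_s": period_s,
                               "n_spikes": n_spikes, "f_start_hz": f_start_hz,
                               "f_peak_hz": f_peak_hz,
                               "burst_duration_ms": burst_dur})
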
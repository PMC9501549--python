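"""Ca²⁺ pulse-train generator.

Each pulse is an instantaneous amplitude addition of ``A`` µM that then decays
exponentially with constant ``tau``; pulses summate when the inter-pulse
interval is short relative to ``tau``:

    Ca(t) = Ca_basal + A · Σ_{t_i ≤ t} exp(-(t - t_i)/tau)

The four named protocols are the standard plasticity-induction trains: LFS
(1 Hz, 0.4 µM/pulse, 30 pulses), 10 Hz, theta-burst (10 epochs of 4 pulses at
100 Hz, epochs 0.2 s apart), and 100 Hz tetanus (1 µM/pulse, 100 pulses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusProtocol", "make_protocol", "calcium_trace", "PROTOCOL_NAMES"]

PROTOCOL_NAMES = ("LFS", "HZ10", "TBS", "HZ100")


@dataclass(frozen=True)
class StimulusProtocol:
    name: str
    frequency: float            # Hz (intra-epoch frequency for TBS)
    amplitude: float            # µM added per pulse
    n_pulses: int
    Ca_basal: float = 0.1       # µM
    tau: float = 0.05           # s
    # optional epoch structure (theta burst)
    pulses_per_epoch: int | None = None
    inter_epoch_interval: float | None = None   # s, epoch start to epoch start
    n_epochs: int | None = None
    _times: tuple[float, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.amplitude <= 0 or self.tau <= 0:
            raise ValueError("frequency, amplitude and tau must be positive")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")
        object.__setattr__(self, "_times", tuple(self._build_times()))
        t = np.asarray(self._times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    def _build_times(self) -> list[float]:
        if self.pulses_per_epoch is None:
            return [i / self.frequency for i in range(self.n_pulses)]
        dt = 1.0 / self.frequency
        out = []
        for e in range(self.n_epochs):
            t0 = e * self.inter_epoch_interval
            out.extend(t0 + k * dt for k in range(self.pulses_per_epoch))
        return out

    @property
    def pulse_times(self) -> np.ndarray:
        """Pulse onset times, s."""
        return np.asarray(self._times)

    @property
    def train_end(self) -> float:
        """End of train: last pulse plus one inter-pulse interval."""
        return self.pulse_times[-1] + 1.0 / self.frequency

    @property
    def total_duration(self) -> float:
        """Simulated span: train plus 1 s follow-up."""
        return self.train_end + 1.0

    def to_config(self) -> dict:
        d = {
            "name": self.name, "frequency": self.frequency,
            "amplitude": self.amplitude, "n_pulses": self.n_pulses,
            "Ca_basal": self.Ca_basal, "tau": self.tau,
        }
        if self.pulses_per_epoch is not None:
            d.update(pulses_per_epoch=self.pulses_per_epoch,
                     inter_epoch_interval=self.inter_epoch_interval,
                     n_epochs=self.n_epochs)
        return d


def make_protocol(name: str, *, Ca_basal: float = 0.1, tau: float = 0.05,
                  **overrides) -> StimulusProtocol:
    """Construct one of the four named stimulation protocols.

    ``overrides`` may replace any protocol field (e.g. ``amplitude=0.5`` or
    ``n_pulses=20``).
    """
    key = name.upper().replace("-", "").replace("_", "")
    presets: dict[str, dict] = {
        "LFS": dict(name="LFS", frequency=1.0, amplitude=0.4, n_pulses=30),
        "HZ10": dict(name="HZ10", frequency=10.0, amplitude=1.0, n_pulses=10),
        "HZ100": dict(name="HZ100", frequency=100.0, amplitude=1.0, n_pulses=100),
        "TBS": dict(name="TBS", frequency=100.0, amplitude=1.0, n_pulses=40,
                    pulses_per_epoch=4, inter_epoch_interval=0.2, n_epochs=10),
    }
    aliases = {"1HZ": "LFS", "10HZ": "HZ10", "100HZ": "HZ100"}
    key = aliases.get(key, key)
    if key not in presets:
        raise ValueError(f"unknown protocol name: {name!r} (choose from {PROTOCOL_NAMES})")
    cfg = presets[key] | dict(Ca_basal=Ca_basal, tau=tau) | overrides
    if key == "TBS":
        cfg["n_pulses"] = cfg["pulses_per_epoch"] * cfg["n_epochs"]
    return StimulusProtocol(**cfg)


def calcium_trace(proto: StimulusProtocol, t) -> np.ndarray | float:
    """Ca²⁺ concentration (µM) at time(s) ``t`` (s); vectorized brute-force sum."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    ti = proto.pulse_times
    dt = t[..., None] - ti          # (..., n_pulses)
    contrib = np.where(dt >= 0.0, np.exp(np.minimum(-dt / proto.tau, 0.0)), 0.0)
    ca = proto.Ca_basal + proto.amplitude * contrib.sum(axis=-1)
    return ca if ca.ndim else float(ca)
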
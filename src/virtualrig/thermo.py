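"""Virtual Peltier-thermistor rig.

A two-node lumped thermal plant stands in for the physical stack: the plate
*surface* node (where the specimen sits and the thermistor is clamped) and
the *heat-sink* node (fan-cooled, beneath the Peltier). The Peltier pumps
heat between the nodes at up to ``Q_max`` watts, with cooling derated by
``eta_asym`` (thermoelectric cooling is less efficient than heating):

    C_surf dT_surf/dt =  u*Q_eff - k_surf_sink*(T_surf - T_sink) - k_surf_amb*(T_surf - amb)
    C_sink dT_sink/dt = -u*Q_eff + k_surf_sink*(T_surf - T_sink) - k_sink_amb_fan*(T_sink - amb)

The pumped heat and the surface-sink conduction appear with opposite signs
in the two equations, so inter-node heat flow is conserved; only the ambient
couplings lose energy. The default parameters are a calibration: the paper
behind this rig reports loop performance (about +/-20 degC range around
ambient, ~1 degC/s ramps, held setpoints with s.d. < 1 degC), not plant
physics, so the constants below are chosen to reproduce those figures at
19 degC ambient with the default bang-bang controller.

The thermistor is a standard beta-model NTC in a resistive divider read by a
10-bit ADC; Gaussian sensor noise is added before quantisation. The control
loop runs on a fine Euler step (10 ms), updates the controller at 10 Hz and
logs setpoint/reading/drive at 2 Hz, as the physical firmware streams them
over serial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .stackio import make_output_path

__all__ = [
    "ThermoParams",
    "ControllerConfig",
    "ControllerState",
    "ThermoLog",
    "plant_step",
    "stability_bound_s",
    "thermistor_model",
    "controller_update",
    "run_loop",
    "loop_stats",
    "LoopStats",
    "steady_state_offsets",
]

KELVIN = 273.15


@dataclass(frozen=True)
class ThermoParams:
    """Lumped plant parameters (calibrated defaults, see module docstring).

    Units: heat capacities J/degC, conductances W/degC, Q_max W.
    """

    C_surf: float = 12.0
    C_sink: float = 200.0
    k_surf_sink: float = 0.5
    k_surf_amb: float = 0.3
    k_sink_amb_fan: float = 2.0
    Q_max: float = 28.0
    eta_asym: float = 0.7
    ambient_C: float = 19.0

    def __post_init__(self) -> None:
        for name in ("C_surf", "C_sink", "k_surf_sink", "k_surf_amb", "k_sink_amb_fan", "Q_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.eta_asym <= 1:
            raise ValueError("eta_asym must lie in (0, 1]")


@dataclass(frozen=True)
class ControllerConfig:
    """Feedback law: bang-bang with hysteresis (default) or clamped PI."""

    mode: Literal["bang_bang", "PI"] = "bang_bang"
    hysteresis_C: float = 0.25
    Kp: float = 0.5
    Ki: float = 0.02
    integral_limit: float = 2.0  # anti-windup clamp on the integral term
    update_period_s: float = 0.1

    def __post_init__(self) -> None:
        if self.hysteresis_C <= 0:
            raise ValueError("hysteresis_C must be > 0")
        if self.update_period_s <= 0:
            raise ValueError("update_period_s must be > 0")


@dataclass
class ControllerState:
    u: float = 0.0
    integral: float = 0.0


@dataclass
class ThermoLog:
    """2-Hz log of setpoint, thermistor reading and drive."""

    times_s: np.ndarray
    setpoint_C: np.ndarray
    reading_C: np.ndarray
    drive: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times_s", "setpoint_C", "reading_C", "drive"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.times_s.size
        if any(getattr(self, name).size != n for name in ("setpoint_C", "reading_C", "drive")):
            raise ValueError("log columns must have equal length")
        if n > 1:
            spacing = np.diff(self.times_s)
            if not np.allclose(spacing, spacing[0]):
                raise ValueError("log must be uniformly spaced")

    def __len__(self) -> int:
        return self.times_s.size

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s,setpoint_C,reading_C,drive\n")
            for row in zip(self.times_s, self.setpoint_C, self.reading_C, self.drive):
                fh.write(",".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "ThermoLog":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, 0], data[:, 1], data[:, 2], data[:, 3])


# -- plant ---------------------------------------------------------------------


def stability_bound_s(params: ThermoParams) -> float:
    """Explicit-Euler stability bound: dt < 2 / (fastest node rate)."""
    rate_surf = (params.k_surf_sink + params.k_surf_amb) / params.C_surf
    rate_sink = (params.k_surf_sink + params.k_sink_amb_fan) / params.C_sink
    return 2.0 / max(rate_surf, rate_sink)


def heat_flows(state: tuple[float, float], u: float, params: ThermoParams) -> dict:
    """Instantaneous heat flows (W), positive into the surface node."""
    t_surf, t_sink = state
    q_eff = params.Q_max if u >= 0 else params.eta_asym * params.Q_max
    return {
        "pumped": u * q_eff,
        "surf_to_sink": params.k_surf_sink * (t_surf - t_sink),
        "surf_to_amb": params.k_surf_amb * (t_surf - params.ambient_C),
        "sink_to_amb": params.k_sink_amb_fan * (t_sink - params.ambient_C),
    }


def plant_step(
    state: tuple[float, float], u: float, params: ThermoParams, dt: float
) -> tuple[float, float]:
    """One explicit-Euler step of the two-node plant.

    ``state`` is (T_surf, T_sink) in degC; ``u`` in [-1, +1] is the drive
    (positive heats the surface). ``dt`` must respect the stability bound.
    """
    if not -1.0 <= u <= 1.0:
        raise ValueError("drive u must lie in [-1, 1]")
    bound = stability_bound_s(params)
    if dt > bound:
        raise ValueError(f"dt={dt} s exceeds the explicit-Euler stability bound {bound:.2f} s")
    t_surf, t_sink = state
    q = heat_flows(state, u, params)
    d_surf = (q["pumped"] - q["surf_to_sink"] - q["surf_to_amb"]) / params.C_surf
    d_sink = (-q["pumped"] + q["surf_to_sink"] - q["sink_to_amb"]) / params.C_sink
    return (t_surf + dt * d_surf, t_sink + dt * d_sink)


def steady_state_offsets(params: ThermoParams) -> tuple[float, float]:
    """Closed-form full-drive steady-state surface offsets from ambient:
    (heating offset > 0, cooling offset < 0)."""

    def solve(q: float) -> float:
        # 0 =  q - kss*(x - y) - ksa*x ;  0 = -q + kss*(x - y) - kf*y
        kss, ksa, kf = params.k_surf_sink, params.k_surf_amb, params.k_sink_amb_fan
        a = np.array([[kss + ksa, -kss], [kss, -(kss + kf)]])
        b = np.array([q, q])
        x, _y = np.linalg.solve(a, b)
        return float(x)

    return solve(params.Q_max), solve(-params.eta_asym * params.Q_max)


# -- sensor --------------------------------------------------------------------


def thermistor_model(
    T_true_C: float,
    adc_bits: int = 10,
    beta_K: float = 3950.0,
    r25_ohm: float = 10_000.0,
    divider_ohm: float = 10_000.0,
    noise_sd_C: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Measure a temperature through the NTC-divider-ADC chain.

    Beta model: R(T) = r25 * exp(beta * (1/T_K - 1/298.15)). The divider
    voltage fraction divider/(divider + R) is quantised to ``adc_bits`` and
    inverted back to degC. Gaussian sensor noise (``noise_sd_C``) perturbs the
    true temperature before quantisation. Valid for T in [-40, 120] degC.
    """
    if not -40.0 <= T_true_C <= 120.0:
        raise ValueError(f"temperature {T_true_C} degC outside the model's validity range")
    t = T_true_C
    if noise_sd_C > 0:
        t = t + (rng or np.random.default_rng()).normal(0.0, noise_sd_C)
    t_k = t + KELVIN
    r = r25_ohm * math.exp(beta_K * (1.0 / t_k - 1.0 / (25.0 + KELVIN)))
    frac = divider_ohm / (divider_ohm + r)
    levels = (1 << adc_bits) - 1
    code = min(max(int(round(frac * levels)), 1), levels - 1)
    frac_q = code / levels
    r_meas = divider_ohm * (1.0 - frac_q) / frac_q
    t_meas_k = 1.0 / (1.0 / (25.0 + KELVIN) + math.log(r_meas / r25_ohm) / beta_K)
    return t_meas_k - KELVIN


# -- controller ----------------------------------------------------------------


def controller_update(
    cfg: ControllerConfig, setpoint_C: float, measured_C: float, state: ControllerState
) -> tuple[float, ControllerState]:
    """One controller tick; returns the drive and the updated state.

    Bang-bang drives full heat below the hysteresis band, full cool above it,
    and retains the previous drive inside the band. PI is proportional plus
    clamped integral, output clamped to [-1, 1].
    """
    error = setpoint_C - measured_C
    if cfg.mode == "bang_bang":
        if measured_C < setpoint_C - cfg.hysteresis_C:
            u = 1.0
        elif measured_C > setpoint_C + cfg.hysteresis_C:
            u = -1.0
        else:
            u = state.u
        return u, ControllerState(u=u, integral=0.0)
    if cfg.mode == "PI":
        integral = state.integral + error * cfg.update_period_s
        integral = max(-cfg.integral_limit, min(cfg.integral_limit, integral))
        u = max(-1.0, min(1.0, cfg.Kp * error + cfg.Ki * integral))
        return u, ControllerState(u=u, integral=integral)
    raise ValueError(f"unknown controller mode {cfg.mode!r}")


# -- closed loop ---------------------------------------------------------------


def run_loop(
    params: ThermoParams | None = None,
    cfg: ControllerConfig | None = None,
    setpoint_schedule: Sequence[tuple[float, float]] = ((0.0, 19.0),),
    duration_s: float = 60.0,
    log_hz: float = 2.0,
    seed: int = 0,
    dt_s: float = 0.01,
    sensor_noise_sd_C: float = 0.1,
) -> ThermoLog:
    """Integrate plant + sensor + controller and log at ``log_hz``.

    ``setpoint_schedule`` is a list of (start_s, setpoint_C); each setpoint
    holds until the next entry. Deterministic given ``seed``.
    """
    params = params or ThermoParams()
    cfg = cfg or ControllerConfig()
    if not setpoint_schedule:
        raise ValueError("empty setpoint schedule")
    schedule = sorted(setpoint_schedule)
    rng = np.random.default_rng(seed)
    state = (params.ambient_C, params.ambient_C)
    ctrl = ControllerState()
    n_steps = int(round(duration_s / dt_s))
    ctrl_every = max(int(round(cfg.update_period_s / dt_s)), 1)
    log_every = max(int(round(1.0 / (log_hz * dt_s))), 1)
    times, setpoints, readings, drives = [], [], [], []
    measured = params.ambient_C
    sched_idx = 0
    setpoint = schedule[0][1]
    for i in range(n_steps):
        t = i * dt_s
        while sched_idx + 1 < len(schedule) and t >= schedule[sched_idx + 1][0]:
            sched_idx += 1
        setpoint = schedule[sched_idx][1]
        if i % ctrl_every == 0:
            measured = thermistor_model(state[0], noise_sd_C=sensor_noise_sd_C, rng=rng)
            u, ctrl = controller_update(cfg, setpoint, measured, ctrl)
        if i % log_every == 0:
            times.append(t)
            setpoints.append(setpoint)
            readings.append(measured)
            drives.append(ctrl.u)
        state = plant_step(state, ctrl.u, params, dt_s)
    return ThermoLog(times, setpoints, readings, drives)


# -- loop statistics -----------------------------------------------------------


@dataclass(frozen=True)
class EpochStats:
    start_s: float
    end_s: float
    setpoint_C: float
    hold_sd_C: float | None  # None if the epoch never settled
    ramp_rate_C_per_s: float | None  # None for the first epoch / zero-step transitions
    overshoot_C: float


@dataclass
class LoopStats:
    epochs: list[EpochStats]
    min_C: float
    max_C: float

    @property
    def max_hold_sd_C(self) -> float:
        sds = [e.hold_sd_C for e in self.epochs if e.hold_sd_C is not None]
        if not sds:
            raise ValueError("no epoch settled; hold s.d. undefined")
        return max(sds)

    @property
    def mean_ramp_rate_C_per_s(self) -> float:
        rates = [e.ramp_rate_C_per_s for e in self.epochs if e.ramp_rate_C_per_s is not None]
        if not rates:
            raise ValueError("no setpoint transition in log; ramp undefined")
        return float(np.mean(rates))


def loop_stats(
    log: ThermoLog, hysteresis_C: float = 0.25, settle_extra_s: float = 10.0
) -> LoopStats:
    """Per-epoch loop performance from a 2-Hz log.

    Epochs are maximal runs of constant setpoint. Hold s.d. is computed over
    readings after settling (first crossing into setpoint +/- ``hysteresis_C``
    plus ``settle_extra_s``); the 10-90% ramp rate of each transition is
    0.8 x |step| divided by the time between the 10% and 90% level crossings;
    overshoot is the maximum excursion beyond the setpoint in the step
    direction.
    """
    t, sp, rd = log.times_s, log.setpoint_C, log.reading_C
    if len(log) == 0:
        raise ValueError("empty log")
    changes = [0] + [i for i in range(1, len(log)) if sp[i] != sp[i - 1]] + [len(log)]
    epochs: list[EpochStats] = []
    for e0, e1 in zip(changes[:-1], changes[1:]):
        setpoint = sp[e0]
        seg_t, seg_r = t[e0:e1], rd[e0:e1]
        prev = rd[e0 - 1] if e0 > 0 else seg_r[0]
        step = setpoint - prev
        # settling: first entry into the hysteresis band, plus margin
        inside = np.nonzero(np.abs(seg_r - setpoint) <= hysteresis_C)[0]
        hold_sd = None
        if inside.size:
            settle_t = seg_t[inside[0]] + settle_extra_s
            held = seg_r[seg_t >= settle_t]
            if held.size >= 2:
                hold_sd = float(np.std(held))
        ramp = None
        if e0 > 0 and abs(step) > 1e-9:
            lo, hi = prev + 0.1 * step, prev + 0.9 * step
            sgn = np.sign(step)
            cross_lo = np.nonzero(sgn * (seg_r - lo) >= 0)[0]
            cross_hi = np.nonzero(sgn * (seg_r - hi) >= 0)[0]
            if cross_lo.size and cross_hi.size and seg_t[cross_hi[0]] > seg_t[cross_lo[0]]:
                ramp = float(0.8 * abs(step) / (seg_t[cross_hi[0]] - seg_t[cross_lo[0]]))
        if e0 > 0 and abs(step) > 1e-9:
            overshoot = float(max((np.sign(step) * (seg_r - setpoint)).max(initial=-np.inf), 0.0))
        elif inside.size:
            # no transition into this epoch: report the excursion beyond the
            # setpoint once the band has first been reached
            overshoot = float(np.max(np.abs(seg_r[inside[0] :] - setpoint)))
        else:
            overshoot = float("nan")
        epochs.append(
            EpochStats(
                start_s=float(seg_t[0]),
                end_s=float(seg_t[-1]),
                setpoint_C=float(setpoint),
                hold_sd_C=hold_sd,
                ramp_rate_C_per_s=ramp,
                overshoot_C=overshoot,
            )
        )
    return LoopStats(epochs=epochs, min_C=float(rd.min()), max_C=float(rd.max()))
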
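"""Stimulus protocol engine and device emulation.

A protocol is a list of :class:`ProtocolStep` entries, each driving one
channel (an LED-ring colour, the LED matrix, the Peltier setpoint or a
general-purpose port) with an on/off looping pattern. Compilation turns the
steps into an :class:`EventLog` of exact integer-microsecond events — all
timing arithmetic is integer, so a million repeats accumulate zero drift.
Execution dispatches the events on a virtual clock to registered channel
handlers (an LED ring model, a thermo setpoint collector, or a null device),
replacing the wall-clock microcontroller of the physical rig.

The ASCII serial grammar (``RING r g b``, ``PELT SET <0.1 °C units>``,
``SERVO id pos``, ``LOG ON|OFF``) is this package's own documented dialect,
not a wire-compatible clone of any firmware.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ProtocolStep",
    "Event",
    "EventLog",
    "LEDRingState",
    "VirtualClock",
    "compile_protocol",
    "protocol_duration_us",
    "run_protocol",
    "stimulus_intervals",
    "format_command",
    "parse_command",
    "CommandError",
    "RingCommand",
    "PeltSetCommand",
    "ServoCommand",
    "LogCommand",
    "ring_preset",
    "RING_PRESETS",
    "load_protocol",
    "save_protocol",
]

_CHANNELS = ("led_ring.red", "led_ring.green", "led_ring.blue", "led_matrix", "peltier.setpoint")
_GPP_RE = re.compile(r"^gpp\.\d+$")


def _valid_channel(channel: str) -> bool:
    return channel in _CHANNELS or bool(_GPP_RE.match(channel))


@dataclass(frozen=True)
class ProtocolStep:
    """One looping pattern: drive ``channel`` at ``value`` for ``on_duration_us``,
    then off for ``off_duration_us``, ``repeats`` times."""

    channel: str
    value: float
    on_duration_us: int
    off_duration_us: int = 0
    repeats: int = 1

    def __post_init__(self) -> None:
        if not _valid_channel(self.channel):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.on_duration_us < 0 or self.off_duration_us < 0:
            raise ValueError("durations must be >= 0")
        if self.on_duration_us == 0 and self.off_duration_us == 0:
            raise ValueError("on and off durations cannot both be zero")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if int(self.on_duration_us) != self.on_duration_us or int(self.off_duration_us) != self.off_duration_us:
            raise ValueError("durations must be integer microseconds")


@dataclass(frozen=True)
class Event:
    t_us: int
    channel: str
    value: float


@dataclass
class EventLog:
    """Ordered microsecond-stamped channel events."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.t_us for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event timestamps must be non-decreasing")
        if any(int(e.t_us) != e.t_us for e in self.events):
            raise ValueError("event timestamps must be integer microseconds")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def span_us(self) -> int:
        return self.events[-1].t_us if self.events else 0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_us,channel,value\n")
            for e in self.events:
                fh.write(f"{e.t_us},{e.channel},{e.value!r}\n")


def protocol_duration_us(steps: Sequence[ProtocolStep]) -> int:
    """Closed-form total protocol span: sum of repeats x (on + off)."""
    return sum(s.repeats * (s.on_duration_us + s.off_duration_us) for s in steps)


def compile_protocol(steps: Sequence[ProtocolStep]) -> EventLog:
    """Compile steps into an event log; steps run sequentially, each repeat
    emits an on event then an off event, in exact integer arithmetic."""
    events: list[Event] = []
    t = 0
    for step in steps:
        for _ in range(step.repeats):
            events.append(Event(t, step.channel, step.value))
            events.append(Event(t + step.on_duration_us, step.channel, 0))
            t += step.on_duration_us + step.off_duration_us
    return EventLog(events)


class VirtualClock:
    """Monotonic integer-microsecond clock decoupled from wall time."""

    def __init__(self) -> None:
        self.now_us: int = 0

    def advance_to(self, t_us: int) -> None:
        if t_us < self.now_us:
            raise ValueError(f"clock cannot run backwards ({t_us} < {self.now_us})")
        self.now_us = int(t_us)


def run_protocol(
    log: EventLog,
    device: dict[str, Callable[[int, float], None]],
    clock: VirtualClock | None = None,
) -> EventLog:
    """Dispatch events in order on a virtual clock.

    ``device`` maps channel names to handlers called as ``handler(t_us, value)``.
    Returns the executed log (equal to the compiled input log).
    """
    clock = clock or VirtualClock()
    executed: list[Event] = []
    for event in log:
        if event.channel not in device:
            raise KeyError(f"event addressed to unregistered channel {event.channel!r}")
        clock.advance_to(event.t_us)
        device[event.channel](event.t_us, event.value)
        executed.append(event)
    return EventLog(executed)


def stimulus_intervals(log: EventLog, channel: str) -> list[tuple[float, float]]:
    """Collapse a channel's on/off events into (onset_s, end_s) intervals."""
    intervals: list[tuple[float, float]] = []
    on_since: int | None = None
    for e in log:
        if e.channel != channel:
            continue
        if e.value > 0 and on_since is None:
            on_since = e.t_us
        elif e.value == 0 and on_since is not None:
            intervals.append((on_since / 1e6, e.t_us / 1e6))
            on_since = None
    return intervals


# -- serial command grammar ----------------------------------------------------


class CommandError(ValueError):
    """Malformed serial line; the message names the offending token."""


@dataclass(frozen=True)
class RingCommand:
    r: int
    g: int
    b: int


@dataclass(frozen=True)
class PeltSetCommand:
    setpoint_C: float  # carried on the wire as a x10 fixed-point integer


@dataclass(frozen=True)
class ServoCommand:
    servo_id: int
    position: int


@dataclass(frozen=True)
class LogCommand:
    enabled: bool


Command = RingCommand | PeltSetCommand | ServoCommand | LogCommand


def format_command(cmd: Command) -> str:
    if isinstance(cmd, RingCommand):
        return f"RING {cmd.r} {cmd.g} {cmd.b}"
    if isinstance(cmd, PeltSetCommand):
        return f"PELT SET {round(cmd.setpoint_C * 10)}"
    if isinstance(cmd, ServoCommand):
        return f"SERVO {cmd.servo_id} {cmd.position}"
    if isinstance(cmd, LogCommand):
        return f"LOG {'ON' if cmd.enabled else 'OFF'}"
    raise CommandError(f"unknown command object {cmd!r}")


def _int_token(token: str, lo: int, hi: int, what: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise CommandError(f"invalid {what} token {token!r}: not an integer") from None
    if not lo <= value <= hi:
        raise CommandError(f"{what} {value} out of range [{lo}, {hi}]")
    return value


def parse_command(line: str) -> Command:
    """Parse one newline-terminated ASCII line into a command object.

    ``parse_command(format_command(c)) == c`` for every valid command.
    """
    tokens = line.strip().split()
    if not tokens:
        raise CommandError("empty command line")
    verb = tokens[0]
    if verb == "RING":
        if len(tokens) != 4:
            raise CommandError("RING expects 3 arguments: r g b")
        r, g, b = (_int_token(t, 0, 255, "intensity") for t in tokens[1:])
        return RingCommand(r, g, b)
    if verb == "PELT":
        if len(tokens) != 3 or tokens[1] != "SET":
            raise CommandError("PELT expects 'SET <setpoint x10>'")
        raw = _int_token(tokens[2], -400, 1200, "setpoint")
        return PeltSetCommand(raw / 10.0)
    if verb == "SERVO":
        if len(tokens) != 3:
            raise CommandError("SERVO expects 2 arguments: id pos")
        return ServoCommand(
            _int_token(tokens[1], 0, 15, "servo id"), _int_token(tokens[2], 0, 180, "position")
        )
    if verb == "LOG":
        if len(tokens) != 2 or tokens[1] not in ("ON", "OFF"):
            raise CommandError("LOG expects ON or OFF")
        return LogCommand(tokens[1] == "ON")
    raise CommandError(f"unknown verb {verb!r}")


# -- LED ring ------------------------------------------------------------------

N_RING_PIXELS = 12


@dataclass
class LEDRingState:
    """State of the 12-pixel RGB LED ring."""

    pixels: np.ndarray  # (12, 3) uint8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (N_RING_PIXELS, 3):
            raise ValueError("LED ring has exactly 12 RGB pixels")

    def __eq__(self, other) -> bool:
        return isinstance(other, LEDRingState) and np.array_equal(self.pixels, other.pixels)


RING_PRESETS = {
    "all_blue_full": (0, 0, 255),
    "all_red_full": (255, 0, 0),
    "all_green_full": (0, 255, 0),
    "dim_red": (20, 0, 0),
    "white": (255, 255, 255),
    "off": (0, 0, 0),
}


def ring_preset(name: str) -> LEDRingState:
    """Uniform ring states used in the optogenetics workflows (e.g. all 12
    blue LEDs at maximum; dim red for undisturbed behavioural tracking)."""
    try:
        rgb = RING_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(RING_PRESETS)}") from None
    return LEDRingState(np.tile(np.array(rgb, dtype=np.uint8), (N_RING_PIXELS, 1)))


# -- protocol files ------------------------------------------------------------


def load_protocol(path) -> list[ProtocolStep]:
    """Load a protocol from YAML/JSON: a list of step mappings."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("protocol file must hold a list of steps")
    return [ProtocolStep(**entry) for entry in raw]


def save_protocol(steps: Iterable[ProtocolStep], path) -> None:
    import yaml

    entries = [
        {
            "channel": s.channel,
            "value": s.value,
            "on_duration_us": s.on_duration_us,
            "off_duration_us": s.off_duration_us,
            "repeats": s.repeats,
        }
        for s in steps
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh)
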
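"""Pluggable pump back-ends receiving :class:`~cytoloop.controller.PumpCommand`.

Two implementations of the same contract: a mock that records every command
(for tests and dry runs), and a serial-line text protocol speaking
``RATE <ml_per_hr>\\n`` to the pump microcontroller and expecting an
``OK\\n`` acknowledgment within a timeout.  The serial actuator talks to any
transport object exposing ``write(bytes)`` and ``readline() -> bytes`` —
a pyserial ``Serial`` instance satisfies this, as does an in-memory loopback.
A command that is not acknowledged is retried once, then raises
:class:`~cytoloop.errors.ActuatorAlarm`; the caller must assume the pump
stopped.
"""

from __future__ import annotations

from typing import Protocol

from .controller import PumpCommand
from .errors import ActuatorAlarm


class Actuator(Protocol):
    def send(self, command: PumpCommand) -> None: ...

    def stop(self) -> None: ...


class MockActuator:
    """Records commands; the test double and dry-run back-end."""

    def __init__(self):
        self.commands: list[PumpCommand] = []

    def send(self, command: PumpCommand) -> None:
        self.commands.append(command)

    def stop(self) -> None:
        self.send(PumpCommand(t=float("nan"), rate=0.0, cause="shutdown"))

    @property
    def rates(self) -> list[float]:
        return [c.rate for c in self.commands]


class SerialActuator:
    """Text protocol over a byte transport (serial port or loopback).

    Parameters
    ----------
    transport : object
        Anything with ``write(bytes) -> int`` and ``readline() -> bytes``;
        the transport owns the timeout (e.g. pyserial's ``timeout=``).
    retries : int
        Extra attempts after a missing/garbled acknowledgment (default 1).
    """

    def __init__(self, transport, retries: int = 1):
        self.transport = transport
        self.retries = retries

    def send(self, command: PumpCommand) -> None:
        line = f"RATE {command.rate:g}\n".encode("ascii")
        for attempt in range(self.retries + 1):
            self.transport.write(line)
            ack = self.transport.readline()
            if ack.strip() == b"OK":
                return
        raise ActuatorAlarm(
            f"pump did not acknowledge {line!r} after "
            f"{self.retries + 1} attempts; assume pump stopped")

    def stop(self) -> None:
        self.send(PumpCommand(t=float("nan"), rate=0.0, cause="shutdown"))
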
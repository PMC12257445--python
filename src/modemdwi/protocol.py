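"""Pulsed-gradient spin-echo (PGSE) acquisition protocols.

A Stejskal-Tanner PGSE experiment applies two rectangular gradient lobes of
amplitude ``Gd``, width ``delta`` and leading-edge separation ``Delta``.  The
diffusion weighting is

    b = (gamma * Gd * delta)**2 * (Delta - delta/3)

with ``gamma`` the proton gyromagnetic ratio.  All public quantities use the
units conventional in the field: b in s/mm^2, Gd in mT/m, times in ms,
gamma in rad s^-1 T^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_PROTON = 2.675e8

#: The 13-b-value simulation protocol (s/mm^2).
B_VALUES_SIM = (0.0, 50.0, 100.0, 150.0, 200.0, 500.0, 800.0, 1000.0,
                1200.0, 1500.0, 2000.0, 2500.0, 3000.0)

#: The 17-b-value clinical-style protocol (s/mm^2).
B_VALUES_CLINICAL = (0.0, 50.0, 80.0, 100.0, 150.0, 200.0, 300.0, 500.0,
                     800.0, 1000.0, 1300.0, 1700.0, 2400.0, 3000.0, 3600.0,
                     4000.0, 4500.0)


def gd_from_b(b: float, *, delta_ms: float, Delta_ms: float,
              gamma: float = GAMMA_PROTON) -> float:
    """Gradient amplitude (mT/m) producing diffusion weighting ``b`` (s/mm^2).

    Inverts b = (gamma Gd delta)^2 (Delta - delta/3).  Raises ``ValueError``
    for infeasible timing (Delta <= delta/3) or negative b.
    """
    if b < 0:
        raise ValueError(f"negative b-value: {b}")
    delta_s = delta_ms * 1e-3
    Delta_s = Delta_ms * 1e-3
    eff = Delta_s - delta_s / 3.0
    if eff <= 0:
        raise ValueError(
            f"infeasible PGSE timing: Delta={Delta_ms} ms, delta={delta_ms} ms "
            "(requires Delta > delta/3)")
    b_si = b * 1e6  # s/mm^2 -> s/m^2
    gd_si = np.sqrt(b_si / eff) / (gamma * delta_s)  # T/m
    return float(gd_si * 1e3)  # mT/m


def b_from_gd(gd_mT_m: float, *, delta_ms: float, Delta_ms: float,
              gamma: float = GAMMA_PROTON) -> float:
    """Diffusion weighting (s/mm^2) from gradient amplitude (mT/m)."""
    delta_s = delta_ms * 1e-3
    Delta_s = Delta_ms * 1e-3
    gd_si = gd_mT_m * 1e-3
    b_si = (gamma * gd_si * delta_s) ** 2 * (Delta_s - delta_s / 3.0)
    return float(b_si * 1e-6)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """b-value list plus the PGSE timing that realizes it.

    Default timing (TE = 85 ms, delta = 25 ms, Delta = 50 ms) is feasible for
    every default b-value at clinically realistic gradient amplitudes.
    """

    b_values: tuple[float, ...] = B_VALUES_SIM
    delta_ms: float = 25.0
    Delta_ms: float = 50.0
    echo_time_ms: float = 85.0
    gamma: float = GAMMA_PROTON
    gradient_amplitudes: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if self.Delta_ms + self.delta_ms > self.echo_time_ms:
            raise ValueError(
                f"Delta + delta = {self.Delta_ms + self.delta_ms} ms exceeds "
                f"TE = {self.echo_time_ms} ms")
        gd = tuple(gd_from_b(bi, delta_ms=self.delta_ms, Delta_ms=self.Delta_ms,
                             gamma=self.gamma) for bi in b)
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        object.__setattr__(self, "gradient_amplitudes", gd)

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "b_values": list(self.b_values),
            "delta_ms": self.delta_ms,
            "Delta_ms": self.Delta_ms,
            "echo_time_ms": self.echo_time_ms,
            "gamma": self.gamma,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionProtocol":
        doc = json.loads(Path(path).read_text())
        return cls(b_values=tuple(doc["b_values"]),
                   delta_ms=doc["delta_ms"], Delta_ms=doc["Delta_ms"],
                   echo_time_ms=doc["echo_time_ms"],
                   gamma=doc.get("gamma", GAMMA_PROTON))
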
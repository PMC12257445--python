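"""Monte-Carlo random-walk synthesis of PGSE diffusion signals.

Walkers take fixed-length steps (L = sqrt(4 D0 dt)) in uniformly random
directions within the 2D plane transverse to the cylinder axes.  Because the
diffusion gradient is applied perpendicular to infinitely long parallel
cylinders, the axial coordinate never enters the accumulated phase, so the
walk is executed in 2D with no loss of generality.

On intersecting a membrane a walker transmits with the substrate's transit
probability and otherwise reflects specularly (or rejects the step, in
``reject`` mode); at most one membrane interaction is resolved per step,
which is accurate for the small default step size.

Each walker accumulates the gradient first moment q = sum_i w_i x_i with
w_i the signed per-step coverage of the rectangular PGSE lobes; the phase at
gradient amplitude Gd is then phi = gamma * Gd * q and the signal is the
magnitude of the ensemble-average phasor  S(b) = |mean_w exp(i phi_w)|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .protocol import AcquisitionProtocol
from .substrates import CylinderSubstrate, SubstrateSpec, build_substrate

#: Scaled-down test profile (walkers, steps) and the full study profile.
PROFILE_CI = (2_000, 2_000)
PROFILE_FULL = (100_000, 20_000)


@dataclass(frozen=True)
class WalkerConfig:
    """Random-walk ensemble configuration."""

    n_walkers: int = PROFILE_CI[0]
    n_steps: int = PROFILE_CI[1]
    seed: int = 0
    reflection_mode: str = "specular"  # or "reject"

    def __post_init__(self) -> None:
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.reflection_mode not in ("specular", "reject"):
            raise ValueError(f"unknown reflection_mode: {self.reflection_mode!r}")

    @classmethod
    def from_profile(cls, profile: str, seed: int = 0) -> "WalkerConfig":
        w, s = PROFILE_FULL if profile == "full" else PROFILE_CI
        return cls(n_walkers=w, n_steps=s, seed=seed)


@dataclass
class SyntheticSignalSet:
    """Noiseless normalized signals S(b)/S0 for one substrate realization."""

    substrate_id: str
    b_values: tuple[float, ...]
    signals: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite signal values")


def step_length_um(d0_mm2_s: float, dt_ms: float) -> float:
    """Fixed step length sqrt(4 D0 dt) in um (D0 in mm^2/s, dt in ms)."""
    d0_um2_ms = d0_mm2_s * 1e3  # 1 mm^2/s = 1e3 um^2/ms
    return math.sqrt(4.0 * d0_um2_ms * dt_ms)


def gradient_weights(protocol: AcquisitionProtocol, n_steps: int) -> np.ndarray:
    """Per-step signed coverage (ms) of the two rectangular PGSE lobes.

    Lobe 1 (+) occupies [0, delta], lobe 2 (-) occupies [Delta, Delta+delta].
    Partial overlap of a step interval with a lobe is weighted fractionally,
    and the weights are de-meaned so the two lobes balance exactly; the
    phase is then insensitive to the absolute walker position.
    """
    te = protocol.echo_time_ms
    dt = te / n_steps
    edges = np.arange(n_steps + 1) * dt

    def overlap(lo: float, hi: float) -> np.ndarray:
        a = np.clip(edges[1:], lo, hi)
        b = np.clip(edges[:-1], lo, hi)
        return a - b

    w = overlap(0.0, protocol.delta_ms)
    w -= overlap(protocol.Delta_ms, protocol.Delta_ms + protocol.delta_ms)
    w -= w.mean()
    return w


@njit(cache=True)
def _containing(x, y, cx, cy, rad, lx, ly, ncx, ncy, cell_start, cell_items):
    gx = int(x / lx * ncx) % ncx
    gy = int(y / ly * ncy) % ncy
    for oy in range(-1, 2):
        for ox in range(-1, 2):
            cell = ((gy + oy) % ncy) * ncx + (gx + ox) % ncx
            for t in range(cell_start[cell], cell_start[cell + 1]):
                j = cell_items[t]
                dx = cx[j] - x
                dx -= lx * round(dx / lx)
                dy = cy[j] - y
                dy -= ly * round(dy / ly)
                if dx * dx + dy * dy <= rad[j] * rad[j]:
                    return j
    return -1


@njit(cache=True)
def _walk(seed, n_walkers, n_steps, step, weights, cx, cy, rad,
          lx, ly, ncx, ncy, cell_start, cell_items, p_transit, reject_mode):
    """Run the ensemble; return per-walker gradient first moments q (um*ms)."""
    np.random.seed(seed)
    q = np.empty(n_walkers)
    n_cyl = rad.shape[0]
    for w in range(n_walkers):
        x = np.random.uniform(0.0, lx)
        y = np.random.uniform(0.0, ly)
        if n_cyl > 0:
            inside = _containing(x, y, cx, cy, rad, lx, ly, ncx, ncy,
                                 cell_start, cell_items)
        else:
            inside = -1
        xw = x  # unwrapped x-coordinate, accumulates phase
        qacc = 0.0
        for i in range(n_steps):
            qacc += weights[i] * xw
            theta = np.random.uniform(0.0, 2.0 * np.pi)
            dx = step * math.cos(theta)
            dy = step * math.sin(theta)
            fdx = dx
            fdy = dy
            if n_cyl > 0:
                if inside >= 0:
                    # possible exit through the membrane of cylinder `inside`
                    j = inside
                    ox = cx[j] - x
                    ox -= lx * round(ox / lx)
                    oy = cy[j] - y
                    oy -= ly * round(oy / ly)
                    ex = dx - ox
                    ey = dy - oy
                    if ex * ex + ey * ey > rad[j] * rad[j]:
                        # endpoint outside: solve |t d - o|^2 = r^2, take t2
                        bq = dx * ox + dy * oy
                        cq = ox * ox + oy * oy - rad[j] * rad[j]
                        disc = bq * bq - step * step * cq
                        t2 = (bq + math.sqrt(max(disc, 0.0))) / (step * step)
                        if t2 < 0.0:
                            t2 = 0.0
                        elif t2 > 1.0:
                            t2 = 1.0
                        if np.random.uniform(0.0, 1.0) < p_transit:
                            inside = -2  # recompute containment after move
                        elif reject_mode == 1:
                            fdx = 0.0
                            fdy = 0.0
                        else:
                            hx = t2 * dx
                            hy = t2 * dy
                            nx_ = (hx - ox) / rad[j]
                            ny_ = (hy - oy) / rad[j]
                            vx = (1.0 - t2) * dx
                            vy = (1.0 - t2) * dy
                            dot = vx * nx_ + vy * ny_
                            fdx = hx + vx - 2.0 * dot * nx_
                            fdy = hy + vy - 2.0 * dot * ny_
                else:
                    # outside: nearest entry intersection among neighbors
                    gx = int(x / lx * ncx) % ncx
                    gy = int(y / ly * ncy) % ncy
                    tmin = 2.0
                    jhit = -1
                    oxh = 0.0
                    oyh = 0.0
                    for oy2 in range(-1, 2):
                        for ox2 in range(-1, 2):
                            cell = ((gy + oy2) % ncy) * ncx + (gx + ox2) % ncx
                            for tt in range(cell_start[cell],
                                            cell_start[cell + 1]):
                                j = cell_items[tt]
                                ox = cx[j] - x
                                ox -= lx * round(ox / lx)
                                oy = cy[j] - y
                                oy -= ly * round(oy / ly)
                                bq = dx * ox + dy * oy
                                if bq <= 0.0:
                                    continue  # moving away
                                cq = ox * ox + oy * oy - rad[j] * rad[j]
                                if cq <= 0.0:
                                    continue  # already inside (numeric)
                                disc = bq * bq - step * step * cq
                                if disc <= 0.0:
                                    continue
                                t1 = (bq - math.sqrt(disc)) / (step * step)
                                if 0.0 <= t1 <= 1.0 and t1 < tmin:
                                    tmin = t1
                                    jhit = j
                                    oxh = ox
                                    oyh = oy
                    if jhit >= 0:
                        if np.random.uniform(0.0, 1.0) < p_transit:
                            inside = -2
                        elif reject_mode == 1:
                            fdx = 0.0
                            fdy = 0.0
                        else:
                            hx = tmin * dx
                            hy = tmin * dy
                            nx_ = (hx - oxh) / rad[jhit]
                            ny_ = (hy - oyh) / rad[jhit]
                            vx = (1.0 - tmin) * dx
                            vy = (1.0 - tmin) * dy
                            dot = vx * nx_ + vy * ny_
                            fdx = hx + vx - 2.0 * dot * nx_
                            fdy = hy + vy - 2.0 * dot * ny_
            x = (x + fdx) % lx
            y = (y + fdy) % ly
            xw += fdx
            if inside == -2:
                inside = _containing(x, y, cx, cy, rad, lx, ly, ncx, ncy,
                                     cell_start, cell_items)
        q[w] = qacc
    return q


def _build_grid(sub: CylinderSubstrate, step: float):
    """CSR cell lists; cell pitch >= r_max + step so 3x3 lookups suffice."""
    lx, ly = sub.box_size
    n = sub.n_cylinders
    rmax = float(sub.radii.max()) if n else 0.0
    h = rmax + 1.001 * step
    ncx = max(1, int(lx / h)) if h > 0 else 1
    ncy = max(1, int(ly / h)) if h > 0 else 1
    gx = (sub.centers[:, 0] / lx * ncx).astype(np.int64) % ncx if n else \
        np.empty(0, np.int64)
    gy = (sub.centers[:, 1] / ly * ncy).astype(np.int64) % ncy if n else \
        np.empty(0, np.int64)
    cell = gy * ncx + gx
    order = np.argsort(cell, kind="stable")
    counts = np.bincount(cell, minlength=ncx * ncy)
    cell_start = np.zeros(ncx * ncy + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    return ncx, ncy, cell_start, order.astype(np.int64)


def simulate_signals(substrate: CylinderSubstrate,
                     protocol: AcquisitionProtocol,
                     walkers: WalkerConfig) -> SyntheticSignalSet:
    """Synthesize the noiseless normalized PGSE signal decay S(b)/S0."""
    dt = protocol.echo_time_ms / walkers.n_steps
    step = step_length_um(substrate.intrinsic_diffusivity, dt)
    if substrate.n_cylinders and step >= substrate.radii.min():
        warnings.warn(
            f"step length {step:.3f} um is not smaller than the smallest "
            f"cylinder radius {substrate.radii.min():.3f} um; refine n_steps",
            stacklevel=2)
    ncx, ncy, cell_start, order = _build_grid(substrate, step)
    n = substrate.n_cylinders
    cx = np.ascontiguousarray(substrate.centers[order, 0]) if n else \
        np.empty(0)
    cy = np.ascontiguousarray(substrate.centers[order, 1]) if n else \
        np.empty(0)
    rad = np.ascontiguousarray(substrate.radii[order]) if n else np.empty(0)
    cell_items = np.arange(n, dtype=np.int64)
    weights = gradient_weights(protocol, walkers.n_steps)
    reject = 1 if walkers.reflection_mode == "reject" else 0

    q = _walk(walkers.seed % (2 ** 32), walkers.n_walkers, walkers.n_steps,
              step, weights, cx, cy, rad,
              float(substrate.box_size[0]), float(substrate.box_size[1]),
              ncx, ncy, cell_start, cell_items,
              float(substrate.permeability_p), reject)
    if not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite walker phase moment")

    signals = np.empty(protocol.n_b)
    for i, gd in enumerate(protocol.gradient_amplitudes):
        if gd == 0.0:
            signals[i] = 1.0
            continue
        # gamma [rad/s/T] * Gd [T/m] * q [um*ms] -> rad  (1e-6 m/um * 1e-3 s/ms)
        phi = protocol.gamma * (gd * 1e-3) * q * 1e-9
        signals[i] = abs(np.mean(np.exp(1j * phi)))
    return SyntheticSignalSet(
        substrate_id=substrate.substrate_id,
        b_values=protocol.b_values,
        signals=signals,
        metadata={"seed": walkers.seed, "n_walkers": walkers.n_walkers,
                  "n_steps": walkers.n_steps, "step_um": step,
                  "achieved_icvf": substrate.achieved_icvf,
                  "permeability_p": substrate.permeability_p})


def generate_dataset(specs: list[SubstrateSpec],
                     protocol: AcquisitionProtocol,
                     walkers: WalkerConfig,
                     n_sim_repeats: int = 10,
                     box_cells: int = 64) -> list[SyntheticSignalSet]:
    """One signal set per (substrate, repeat); seeds spawn from walkers.seed.

    Repeats reuse the substrate geometry and vary the walker initialization,
    mirroring repeated simulation with different random seeds.
    """
    if n_sim_repeats < 1:
        raise ValueError("n_sim_repeats must be >= 1")
    master = np.random.SeedSequence(walkers.seed)
    out: list[SyntheticSignalSet] = []
    for spec_i, spec in enumerate(specs):
        sub_ss, walk_ss = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(spec_i,)).spawn(2)
        sub_seed = int(sub_ss.generate_state(1)[0] % (2 ** 31))
        try:
            substrate = build_substrate(spec, box_cells=box_cells,
                                        seed=sub_seed)
            for rep, rep_ss in enumerate(walk_ss.spawn(n_sim_repeats)):
                wc = WalkerConfig(
                    n_walkers=walkers.n_walkers, n_steps=walkers.n_steps,
                    seed=int(rep_ss.generate_state(1)[0] % (2 ** 31)),
                    reflection_mode=walkers.reflection_mode)
                sset = simulate_signals(substrate, protocol, wc)
                sset.metadata.update(group_id=spec.group_id,
                                     level_index=spec.level_index,
                                     repeat=rep, label=spec.label)
                out.append(sset)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed for substrate {spec.substrate_id}") from exc
    return out
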
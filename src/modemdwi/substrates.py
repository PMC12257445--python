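"""Packed-cylinder tissue substrates for Monte-Carlo diffusion simulation.

A substrate is a periodic 2D box containing non-overlapping disks (the
transverse sections of parallel cylinders standing in for cells).  Four
cellular-property axes are covered, ten levels each:

* cell size       -- uniform radius 2..6 um (small) vs 7..11 um (large)
* cell density    -- intracellular volume fraction (ICVF) 13.5%..74.0%
* size dispersion -- gamma-distributed radii, (k, theta) pairs chosen so the
                     expected intracellular area k(k+1)theta^2 is constant
* permeability    -- membrane transit probability 0%..1.8%

Unspecified properties take the shared defaults: ICVF 58%, uniform radii,
hexagonal packing, transit probability 0.2%, intrinsic diffusivity
2.0e-3 mm^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Maximum area fraction of a hexagonal disk packing, pi / (2 sqrt(3)).
HEX_MAX_ICVF = math.pi / (2.0 * math.sqrt(3.0))

#: Shared substrate defaults.
DEFAULT_ICVF = 0.58
DEFAULT_RADIUS_UM = 5.0
DEFAULT_PERMEABILITY = 0.002
DEFAULT_D0 = 2.0e-3  # mm^2/s

#: Ten ICVF levels for the cell-density axis (fractions).
DENSITY_ICVF_LEVELS = (0.135, 0.202, 0.269, 0.336, 0.404,
                       0.471, 0.538, 0.605, 0.673, 0.740)

#: Ten gamma (shape k, scale theta[m]) pairs for the size-dispersion axis.
GAMMA_LEVELS = ((10.0, 0.43e-6), (9.0, 0.47e-6), (8.0, 0.53e-6),
                (7.0, 0.60e-6), (6.0, 0.69e-6), (5.0, 0.81e-6),
                (4.0, 0.99e-6), (3.0, 1.29e-6), (2.0, 1.82e-6),
                (1.5, 2.30e-6))

#: Ten membrane transit probabilities for the permeability axis.
PERMEABILITY_LEVELS = (0.000, 0.002, 0.004, 0.006, 0.008,
                       0.010, 0.012, 0.014, 0.016, 0.018)

#: Ten uniform radii (um) for the cell-size axis.
RADIUS_LEVELS = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0)

GROUPS = ("cell_size", "cell_density", "size_distribution", "permeability")


@dataclass(frozen=True)
class SubstrateSpec:
    """Geometry and physiology of one simulated tissue substrate.

    Exactly one of ``radius_um`` (uniform radii) or the pair
    ``(gamma_shape_k, gamma_scale_theta_m)`` (gamma-distributed radii) must
    be present.
    """

    group_id: str
    level_index: int
    target_icvf: float = DEFAULT_ICVF
    permeability_p: float = DEFAULT_PERMEABILITY
    intrinsic_diffusivity: float = DEFAULT_D0  # mm^2/s
    radius_um: float | None = DEFAULT_RADIUS_UM
    gamma_shape_k: float | None = None
    gamma_scale_theta_m: float | None = None
    packing: str = "hexagonal"

    def __post_init__(self) -> None:
        if self.group_id not in GROUPS:
            raise ValueError(f"unknown group_id: {self.group_id!r}")
        if not 0 <= self.level_index <= 9:
            raise ValueError(f"level_index out of range: {self.level_index}")
        has_r = self.radius_um is not None
        has_gamma = (self.gamma_shape_k is not None
                     and self.gamma_scale_theta_m is not None)
        if has_r == has_gamma:
            raise ValueError(
                "exactly one of radius_um or (gamma_shape_k, "
                "gamma_scale_theta_m) must be set")
        if not 0.0 < self.target_icvf < 0.91:
            raise ValueError(f"target_icvf out of (0, 0.91): {self.target_icvf}")
        if not 0.0 <= self.permeability_p <= 1.0:
            raise ValueError(f"permeability_p out of [0,1]: {self.permeability_p}")
        if self.packing not in ("hexagonal", "polydisperse_random"):
            raise ValueError(f"unknown packing: {self.packing!r}")

    @property
    def substrate_id(self) -> str:
        return f"{self.group_id}_L{self.level_index}"

    @property
    def label(self) -> int:
        """Binary class: 0 for levels 0-4 (first group), 1 for levels 5-9."""
        return 0 if self.level_index < 5 else 1


@dataclass
class CylinderSubstrate:
    """Realized periodic packing: centers/radii in um, box (Lx, Ly) in um."""

    box_size: tuple[float, float]
    centers: np.ndarray          # (n, 2) um
    radii: np.ndarray            # (n,) um
    achieved_icvf: float
    permeability_p: float
    intrinsic_diffusivity: float = DEFAULT_D0
    substrate_id: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_cylinders(self) -> int:
        return len(self.radii)

    def min_image_distances(self) -> np.ndarray:
        """Pairwise center distances under the periodic minimum image."""
        c = self.centers
        lx, ly = self.box_size
        dx = c[:, None, 0] - c[None, :, 0]
        dy = c[:, None, 1] - c[None, :, 1]
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
        return np.hypot(dx, dy)


def hexagonal_lattice_spacing(radius_um: float, icvf: float) -> float:
    """Lattice constant ``a`` such that 2 pi r^2 / (sqrt(3) a^2) = icvf."""
    return radius_um * math.sqrt(2.0 * math.pi / (math.sqrt(3.0) * icvf))


def enumerate_substrates() -> list[SubstrateSpec]:
    """The full 4-axis x 10-level grid of 40 substrate specifications."""
    specs: list[SubstrateSpec] = []
    for i, r in enumerate(RADIUS_LEVELS):
        specs.append(SubstrateSpec(group_id="cell_size", level_index=i,
                                   radius_um=r))
    for i, phi in enumerate(DENSITY_ICVF_LEVELS):
        specs.append(SubstrateSpec(group_id="cell_density", level_index=i,
                                   target_icvf=phi))
    for i, (k, theta) in enumerate(GAMMA_LEVELS):
        specs.append(SubstrateSpec(group_id="size_distribution", level_index=i,
                                   radius_um=None, gamma_shape_k=k,
                                   gamma_scale_theta_m=theta,
                                   packing="polydisperse_random"))
    for i, p in enumerate(PERMEABILITY_LEVELS):
        specs.append(SubstrateSpec(group_id="permeability", level_index=i,
                                   permeability_p=p))
    return specs


def _build_hexagonal(spec: SubstrateSpec, box_cells: int) -> CylinderSubstrate:
    r = float(spec.radius_um)
    phi = spec.target_icvf
    if phi > HEX_MAX_ICVF:
        raise ValueError(
            f"target ICVF {phi:.4f} exceeds hexagonal packing maximum "
            f"{HEX_MAX_ICVF:.4f}")
    a = hexagonal_lattice_spacing(r, phi)
    # Periodic hexagonal lattice: nx columns, ny rows (ny even), row pitch
    # a*sqrt(3)/2, odd rows offset by a/2.  Choose a roughly square box.
    nx = max(4, math.ceil(math.sqrt(box_cells / 1.1547)))
    ny = max(4, math.ceil(box_cells / nx))
    ny += ny % 2
    lx = nx * a
    ly = ny * a * math.sqrt(3.0) / 2.0
    centers = np.empty((nx * ny, 2))
    idx = 0
    for j in range(ny):
        y = (j + 0.5) * a * math.sqrt(3.0) / 2.0
        xoff = 0.5 * a * (j % 2)
        for i in range(nx):
            centers[idx, 0] = (i + 0.25) * a + xoff
            centers[idx, 1] = y
            idx += 1
    centers[:, 0] %= lx
    radii = np.full(nx * ny, r)
    achieved = nx * ny * math.pi * r * r / (lx * ly)
    return CylinderSubstrate(
        box_size=(lx, ly), centers=centers, radii=radii,
        achieved_icvf=achieved, permeability_p=spec.permeability_p,
        intrinsic_diffusivity=spec.intrinsic_diffusivity,
        substrate_id=spec.substrate_id,
        metadata={"packing": "hexagonal", "lattice_spacing_um": a,
                  "target_icvf": phi})


def sample_gamma_radii(k: float, theta_m: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` radii (um) from Gamma(shape k, scale theta), theta in m."""
    return rng.gamma(shape=k, scale=theta_m * 1e6, size=n)


def _build_polydisperse(spec: SubstrateSpec, box_cells: int, seed: int,
                        max_attempts: int = 100_000,
                        relax_sweeps: int = 2,
                        strict: bool = False) -> CylinderSubstrate:
    rng = np.random.default_rng(seed)
    k = float(spec.gamma_shape_k)
    theta_um = float(spec.gamma_scale_theta_m) * 1e6
    phi = spec.target_icvf
    mean_area = math.pi * k * (k + 1.0) * theta_um ** 2
    box_area = box_cells * mean_area / phi
    lbox = math.sqrt(box_area)
    # Draw radii until the target intracellular area is covered, then place
    # largest-first by random sequential addition (largest-first packs
    # considerably denser, which matters near the RSA jamming density).
    radii: list[float] = []
    area = 0.0
    min_r = 0.25  # um; tiny disks add nothing but cost collision checks
    budget = phi * box_area
    rejected = 0
    while rejected < 200:  # fill the area budget without overshooting it
        r = float(sample_gamma_radii(k, theta_um * 1e-6, 1, rng)[0])
        if r < min_r:
            continue
        a_r = math.pi * r * r
        if area + a_r > budget:
            rejected += 1
            continue
        radii.append(r)
        area += a_r
    radii.sort(reverse=True)

    placed_c: list[tuple[float, float]] = []
    placed_r: list[float] = []

    def overlaps(x: float, y: float, r: float) -> bool:
        for (px, py), pr in zip(placed_c, placed_r):
            dx = x - px
            dx -= lbox * round(dx / lbox)
            dy = y - py
            dy -= lbox * round(dy / lbox)
            if dx * dx + dy * dy < (r + pr) ** 2:
                return True
        return False

    def relax() -> None:
        # One MC sweep of small accepted-if-collision-free displacements.
        for i in range(len(placed_r)):
            x0, y0 = placed_c[i]
            jit = 0.3 * placed_r[i]
            x1 = (x0 + rng.uniform(-jit, jit)) % lbox
            y1 = (y0 + rng.uniform(-jit, jit)) % lbox
            keep_c, keep_r = placed_c.pop(i), placed_r.pop(i)
            if not overlaps(x1, y1, keep_r):
                placed_c.insert(i, (x1, y1))
            else:
                placed_c.insert(i, keep_c)
            placed_r.insert(i, keep_r)

    n_failed = 0
    for r in radii:
        done = False
        for sweep in range(relax_sweeps + 1):
            for _ in range(max_attempts // (relax_sweeps + 1)):
                x = rng.uniform(0.0, lbox)
                y = rng.uniform(0.0, lbox)
                if not overlaps(x, y, r):
                    placed_c.append((x, y))
                    placed_r.append(r)
                    done = True
                    break
            if done:
                break
            if sweep < relax_sweeps:
                relax()
        if not done:
            n_failed += 1
            if strict:
                raise RuntimeError(
                    f"polydisperse placement failed for radius {r:.2f} um "
                    f"after {max_attempts} attempts ({spec.substrate_id})")

    centers = np.array(placed_c, dtype=float).reshape(-1, 2)
    rr = np.array(placed_r, dtype=float)
    achieved = float(np.sum(math.pi * rr ** 2) / box_area)
    return CylinderSubstrate(
        box_size=(lbox, lbox), centers=centers, radii=rr,
        achieved_icvf=achieved, permeability_p=spec.permeability_p,
        intrinsic_diffusivity=spec.intrinsic_diffusivity,
        substrate_id=spec.substrate_id,
        metadata={"packing": "polydisperse_random", "target_icvf": phi,
                  "n_failed_placements": n_failed, "seed": seed})


def build_substrate(spec: SubstrateSpec, box_cells: int = 64, seed: int = 0,
                    **poly_kwargs) -> CylinderSubstrate:
    """Realize a periodic cylinder packing from a substrate specification.

    ``box_cells`` sets the approximate number of cylinders in the periodic
    box (>= 16).  Hexagonal packings achieve the target ICVF exactly;
    polydisperse random sequential packings record the achieved ICVF, which
    is used downstream when the target is unreachable (jamming).
    """
    if box_cells < 16:
        raise ValueError(f"box_cells must be >= 16, got {box_cells}")
    if spec.packing == "hexagonal":
        return _build_hexagonal(spec, box_cells)
    return _build_polydisperse(spec, box_cells, seed, **poly_kwargs)


def empty_substrate(box_um: float = 100.0,
                    d0: float = DEFAULT_D0) -> CylinderSubstrate:
    """A cylinder-free periodic box (free diffusion)."""
    return CylinderSubstrate(
        box_size=(box_um, box_um), centers=np.empty((0, 2)),
        radii=np.empty(0), achieved_icvf=0.0, permeability_p=0.0,
        intrinsic_diffusivity=d0, substrate_id="free",
        metadata={"packing": "none"})
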
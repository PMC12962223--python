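"""Domain types and small-tip-angle excitation simulation.

The excitation model is the standard small-tip-angle (STA) approximation for
multi-channel transmission: the transverse magnetization produced by a train
of Nt hard sub-pulses played on Nc channels is linear in the complex pulse
amplitudes, with per-voxel weights given by the transmit sensitivities, an
off-resonance phase term and the excitation k-space phase of each sub-pulse.
Sensitivities are stored in rad/(V*s) with the gyromagnetic prefactor folded
in, so flip angle in radians is ``|A @ p|`` with ``A`` the system matrix and
``p`` the vectorized pulse in volts.

A channel->coil schedule makes the sensitivity seen by a logical channel
time-dependent, which is what row-switched (time-division-multiplexed)
transmission needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "CoilLabel",
    "ChannelFieldSet",
    "OffResonanceMap",
    "ChannelSchedule",
    "PulseTiming",
    "PulseProgram",
    "FlipAngleMap",
    "SystemMatrix",
    "build_system_matrix",
    "simulate_sta",
    "simulate_bloch",
    "nrmse",
    "cp_mode",
    "scale_mode_to_target",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid with a boolean region-of-interest mask.

    Physical coordinates are voxel centers: ``r = origin + index * spacing``
    (0-based indices, right-handed axes, SI meters).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be 3 positive integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError("mask shape must equal grid shape")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def centered(cls, n: int, spacing: float, mask: np.ndarray | None = None) -> "VoxelGrid":
        """Cubic grid of ``n**3`` voxels centered on the physical origin."""
        origin = -spacing * (n - 1) / 2.0
        if mask is None:
            mask = np.ones((n, n, n), dtype=bool)
        return cls((n, n, n), (spacing,) * 3, (origin,) * 3, mask)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    def coordinates(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape ``shape + (3,)``."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d]
            for d in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def mask_coordinates(self) -> np.ndarray:
        """(N_mask, 3) physical coordinates of in-mask voxel centers."""
        return self.coordinates()[self.mask]

    def scatter(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-mask-voxel vector back onto the full grid."""
        out = np.full(self.shape, fill, dtype=np.asarray(values).dtype)
        out[self.mask] = values
        return out

    def compatible(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and bool(np.array_equal(self.mask, other.mask))
        )


@dataclass(frozen=True)
class CoilLabel:
    """Identity of one physical coil element: row name, 1-based element
    index within the row, and azimuthal position in degrees."""

    row: str
    element: int
    azimuth_deg: float


@dataclass
class ChannelFieldSet:
    """Per-coil complex transmit sensitivities on a voxel grid.

    ``sensitivities`` has shape ``(n_coils,) + grid.shape``, units
    rad/(V*s) (gamma folded in, normalized to input voltage).
    """

    grid: VoxelGrid
    sensitivities: np.ndarray
    labels: Sequence[CoilLabel]

    def __post_init__(self):
        self.sensitivities = np.asarray(self.sensitivities, dtype=complex)
        if self.sensitivities.ndim != 4 or self.sensitivities.shape[1:] != self.grid.shape:
            raise ValueError("sensitivities must have shape (n_coils,) + grid.shape")
        if self.n_coils < 1:
            raise ValueError("need at least one coil")
        if len(self.labels) != self.n_coils:
            raise ValueError("one label per coil required")
        if len({(l.row, l.element) for l in self.labels}) != self.n_coils:
            raise ValueError("coil labels must be unique")
        if not np.all(np.isfinite(self.sensitivities[:, self.grid.mask])):
            raise ValueError("non-finite sensitivity inside mask")

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    def row_indices(self, row: str) -> np.ndarray:
        idx = np.array([i for i, l in enumerate(self.labels) if l.row == row], dtype=int)
        if idx.size == 0:
            raise ValueError(f"no coils in row {row!r}")
        return idx

    @property
    def rows(self) -> list[str]:
        seen: list[str] = []
        for l in self.labels:
            if l.row not in seen:
                seen.append(l.row)
        return seen

    def subset(self, indices: np.ndarray) -> "ChannelFieldSet":
        return ChannelFieldSet(
            self.grid,
            self.sensitivities[indices],
            [self.labels[i] for i in indices],
        )

    def masked(self) -> np.ndarray:
        """(n_coils, N_mask) sensitivities restricted to the mask."""
        return self.sensitivities[:, self.grid.mask]


@dataclass
class OffResonanceMap:
    """Static off-resonance in Hz on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("off-resonance shape must equal grid shape")
        if not np.all(np.isfinite(self.values[self.grid.mask])):
            raise ValueError("non-finite off-resonance inside mask")

    @classmethod
    def zero(cls, grid: VoxelGrid) -> "OffResonanceMap":
        return cls(grid, np.zeros(grid.shape))


@dataclass(frozen=True)
class ChannelSchedule:
    """Per-time-step assignment of logical channels to physical coils.

    ``coil_map[t, c]`` is the physical coil index driven by logical channel
    ``c`` during sub-pulse ``t``. ``step_labels`` optionally tags each step
    with the coil-group name that is live (e.g. ``"top"``/``"bottom"``),
    which SAR evaluation against row-wise Q-matrix sets relies on.
    """

    coil_map: np.ndarray
    step_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        cm = np.asarray(self.coil_map, dtype=int)
        if cm.ndim != 2:
            raise ValueError("coil_map must be (n_steps, n_channels)")
        for t in range(cm.shape[0]):
            if len(set(cm[t].tolist())) != cm.shape[1]:
                raise ValueError("each step must map channels to distinct coils")
        object.__setattr__(self, "coil_map", cm)
        if self.step_labels is not None and len(self.step_labels) != cm.shape[0]:
            raise ValueError("one step label per time step")

    @property
    def n_steps(self) -> int:
        return self.coil_map.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coil_map.shape[1]

    @classmethod
    def static(cls, n_coils: int, n_steps: int, label: str | None = None) -> "ChannelSchedule":
        cm = np.tile(np.arange(n_coils), (n_steps, 1))
        labels = (label,) * n_steps if label is not None else None
        return cls(cm, labels)

    @classmethod
    def cyclic(
        cls, group_maps: Sequence[np.ndarray], n_steps: int,
        group_labels: Sequence[str] | None = None,
    ) -> "ChannelSchedule":
        """Schedule cycling through coil groups: step t uses group t % G."""
        g = len(group_maps)
        cm = np.stack([np.asarray(group_maps[t % g], dtype=int) for t in range(n_steps)])
        labels = None
        if group_labels is not None:
            labels = tuple(group_labels[t % g] for t in range(n_steps))
        return cls(cm, labels)

    def validate_against(self, fields: ChannelFieldSet) -> None:
        if self.coil_map.min() < 0 or self.coil_map.max() >= fields.n_coils:
            raise ValueError("schedule references a coil missing from the field set")


@dataclass(frozen=True)
class PulseTiming:
    """Sub-pulse and sequence timing in seconds.

    ``switch_gap`` separates consecutive sub-pulses when only the
    channel->coil routing changes; ``blip_duration`` separates them when the
    excitation k-space location changes (a gradient blip is played). Neither
    interval carries RF.
    """

    sub_pulse_duration: float
    tr: float
    switch_gap: float = 10e-6
    blip_duration: float = 100e-6

    def __post_init__(self):
        if self.sub_pulse_duration < 0 or self.switch_gap < 0 or self.blip_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.tr <= 0:
            raise ValueError("TR must be positive")


@dataclass
class PulseProgram:
    """A multi-channel pulse: complex sub-pulse amplitudes (volts) per
    (time step, logical channel), per-step k-space locations (1/m), timing
    and the channel->coil schedule."""

    amplitudes: np.ndarray
    k_locations: np.ndarray
    timing: PulseTiming
    schedule: ChannelSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        self.k_locations = np.atleast_2d(np.asarray(self.k_locations, dtype=float))
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be (n_steps, n_channels)")
        if self.k_locations.shape != (self.n_steps, 3):
            raise ValueError("need one 3-vector k-location per time step")
        if self.schedule.n_steps != self.n_steps or self.schedule.n_channels != self.n_channels:
            raise ValueError("schedule shape inconsistent with amplitudes")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_steps(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[1]

    def gap_after(self, j: int) -> float:
        """RF-free interval between sub-pulse j and j+1 (see PulseTiming)."""
        if j < 0 or j >= self.n_steps - 1:
            return 0.0
        if not np.array_equal(self.k_locations[j], self.k_locations[j + 1]):
            return self.timing.blip_duration
        if not np.array_equal(self.schedule.coil_map[j], self.schedule.coil_map[j + 1]):
            return self.timing.switch_gap
        return 0.0

    def step_centers(self) -> np.ndarray:
        """Temporal centers of the sub-pulses on the physical timeline."""
        dt = self.timing.sub_pulse_duration
        t = np.empty(self.n_steps)
        clock = 0.0
        for j in range(self.n_steps):
            t[j] = clock + dt / 2.0
            clock += dt + self.gap_after(j)
        return t

    @property
    def duration(self) -> float:
        """Total pulse duration T including switch gaps and blips."""
        dt = self.timing.sub_pulse_duration
        return self.n_steps * dt + sum(self.gap_after(j) for j in range(self.n_steps - 1))


@dataclass
class FlipAngleMap:
    """Flip angle in degrees per voxel; zero outside the mask."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("flip-angle shape must equal grid shape")
        inside = self.values[self.grid.mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError("non-finite flip angle inside mask")
        if inside.size and inside.min() < 0:
            raise ValueError("flip angle must be non-negative")

    def masked(self) -> np.ndarray:
        return self.values[self.grid.mask]


@dataclass
class SystemMatrix:
    """STA system matrix over mask voxels, factored for fast k updates.

    ``base[i, j, c] = 1j * dt * beta_sched(c,j)(r_i)
                      * exp(1j * 2*pi * dB0(r_i) * (t_j - T))``
    and the full matrix multiplies in the per-step k-space phase
    ``exp(1j * 2*pi * r_i . k_j)``. Column order of the dense matrix is
    C-order of ``(step, channel)``, matching ``amplitudes.ravel()``.
    """

    grid: VoxelGrid
    base: np.ndarray          # (N_mask, n_steps, n_channels) complex
    positions: np.ndarray     # (N_mask, 3) meters
    k_locations: np.ndarray   # (n_steps, 3) 1/m
    dt_steps: np.ndarray      # (n_steps,) seconds

    @property
    def n_steps(self) -> int:
        return self.base.shape[1]

    @property
    def n_channels(self) -> int:
        return self.base.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.base.shape[0], self.n_steps * self.n_channels)

    def k_phase(self, k: np.ndarray) -> np.ndarray:
        """(N_mask, n_steps) phase factors exp(i 2 pi r.k_j)."""
        return np.exp(2j * np.pi * (self.positions @ np.asarray(k, dtype=float).T))

    def matrix(self, k: np.ndarray | None = None) -> np.ndarray:
        """Dense (N_mask, n_steps*n_channels) system matrix."""
        kk = self.k_locations if k is None else np.asarray(k, dtype=float)
        a = self.base * self.k_phase(kk)[:, :, None]
        return a.reshape(self.shape)


def build_system_matrix(
    fields: ChannelFieldSet,
    db0: OffResonanceMap,
    pulse_skeleton: PulseProgram,
) -> SystemMatrix:
    """Assemble the STA system matrix for a pulse skeleton.

    The skeleton supplies timing, schedule and k-locations; its amplitudes
    are ignored. Entry (i, (j, c)) is
    ``1j * dt * beta_{schedule(j,c)}(r_i) * exp(i 2pi dB0_i (t_j - T))
    * exp(i 2pi r_i . k_j)`` with ``t_j`` the sub-pulse center on the
    physical timeline (gaps and blips advance the clock but carry no RF).
    """
    if not fields.grid.compatible(db0.grid):
        raise ValueError("field and off-resonance grids do not match")
    pulse_skeleton.schedule.validate_against(fields)

    grid = fields.grid
    beta = fields.masked()                       # (n_coils, N)
    dvals = db0.values[grid.mask]                # (N,)
    t = pulse_skeleton.step_centers()
    T = pulse_skeleton.duration
    dt = pulse_skeleton.timing.sub_pulse_duration
    nt, nch = pulse_skeleton.n_steps, pulse_skeleton.n_channels

    base = np.empty((beta.shape[1], nt, nch), dtype=complex)
    for j in range(nt):
        phase = np.exp(2j * np.pi * dvals * (t[j] - T))
        sel = beta[pulse_skeleton.schedule.coil_map[j]]  # (n_channels, N)
        base[:, j, :] = (1j * dt) * (sel * phase[None, :]).T
    return SystemMatrix(
        grid=grid,
        base=base,
        positions=grid.mask_coordinates(),
        k_locations=pulse_skeleton.k_locations.copy(),
        dt_steps=np.full(nt, dt),
    )


def simulate_sta(A: SystemMatrix, pulse: PulseProgram) -> FlipAngleMap:
    """Flip-angle map (degrees) of a pulse under the STA model.

    FA(r_i) = |A . vec(p)| converted from radians to degrees; voxels
    outside the mask are zero.
    """
    p = pulse.amplitudes.ravel()
    if p.size != A.shape[1]:
        raise ValueError("pulse amplitude vector does not match system matrix columns")
    fa_rad = np.abs(A.matrix(pulse.k_locations) @ p)
    return FlipAngleMap(A.grid, A.grid.scatter(np.degrees(fa_rad)))


def nrmse(fa: FlipAngleMap, target_deg: float, mask: np.ndarray | None = None) -> float:
    """Root-mean-square flip-angle deviation over the mask, normalized by
    the target: ``sqrt(mean((FA - target)^2)) / target`` (dimensionless)."""
    if target_deg <= 0:
        raise ValueError("target flip angle must be positive")
    m = fa.grid.mask if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    dev = fa.values[m] - target_deg
    return float(np.sqrt(np.mean(dev**2)) / target_deg)


def cp_mode(fields: ChannelFieldSet, amplitude: float = 1.0) -> np.ndarray:
    """Circularly-polarized drive vector: equal magnitudes, per-element
    phase equal to its azimuthal position (same increment in both rows)."""
    phases = np.array([np.deg2rad(l.azimuth_deg) for l in fields.labels])
    return amplitude * np.exp(1j * phases)


def scale_mode_to_target(
    A: SystemMatrix, mode: np.ndarray, target_deg: float
) -> tuple[np.ndarray, float]:
    """Scale a static drive vector so the mask-mean STA flip angle equals
    ``target_deg``. Requires a single-time-step system matrix. Returns the
    scaled mode and the scale factor (linearity of the STA model)."""
    if A.n_steps != 1:
        raise ValueError("mode scaling expects a single-step system matrix")
    fa = np.degrees(np.abs(A.matrix() @ np.asarray(mode, dtype=complex)))
    mean_fa = float(fa.mean())
    if mean_fa == 0:
        raise ValueError("mode excites nothing; cannot scale")
    s = target_deg / mean_fa
    return np.asarray(mode, dtype=complex) * s, s


def _rotate(M: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of per-voxel vectors M (N,3) about per-voxel unit
    axes by per-voxel angles."""
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    k = axis
    kdotm = np.sum(k * M, axis=1, keepdims=True)
    return M * c + np.cross(k, M) * s + k * kdotm * (1 - c)


def _rotate_z(M: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotation about +z by per-voxel angles (counterclockwise: the
    transverse component m_x + i m_y picks up exp(i*angle))."""
    c, s = np.cos(angle), np.sin(angle)
    out = M.copy()
    out[:, 0] = c * M[:, 0] - s * M[:, 1]
    out[:, 1] = s * M[:, 0] + c * M[:, 1]
    return out


def simulate_bloch(
    fields: ChannelFieldSet,
    db0: OffResonanceMap,
    pulse: PulseProgram,
) -> FlipAngleMap:
    """Hard-pulse rotation-matrix Bloch integration (relaxation off).

    Independent of the STA path: each sub-pulse is a rotation about the
    instantaneous effective field built from the summed complex B1 (rad/s)
    and the off-resonance rate; gradient blips apply the z-rotation that
    realizes the change of excitation k-space phase; switch gaps and blips
    advance off-resonance precession. Reported as degrees of total rotation
    away from +z, i.e. arcsin|Mxy| in the small-tip regime.
    """
    if not fields.grid.compatible(db0.grid):
        raise ValueError("field and off-resonance grids do not match")
    pulse.schedule.validate_against(fields)
    grid = fields.grid
    beta = fields.masked()                       # (n_coils, N) rad/(V s)
    omega_z = 2 * np.pi * db0.values[grid.mask]  # rad/s
    r = grid.mask_coordinates()
    n = r.shape[0]
    dt = pulse.timing.sub_pulse_duration

    M = np.zeros((n, 3))
    M[:, 2] = 1.0
    for j in range(pulse.n_steps):
        b1 = beta[pulse.schedule.coil_map[j]].T @ pulse.amplitudes[j]  # (N,) rad/s
        # generator dM/dt = M x Omega with Omega=(Re b1, Im b1, omega_z):
        # rotation about Omega-hat by angle -|Omega| dt reproduces the STA
        # phase conventions used in build_system_matrix.
        om = np.stack([b1.real, b1.imag, np.broadcast_to(omega_z, (n,))], axis=1)
        norm = np.linalg.norm(om, axis=1)
        safe = np.where(norm > 0, norm, 1.0)
        M = _rotate(M, om / safe[:, None], -norm * dt)
        gap = pulse.gap_after(j)
        if gap > 0:
            ang = -omega_z * gap
            if j < pulse.n_steps - 1:
                dk = pulse.k_locations[j] - pulse.k_locations[j + 1]
                ang = ang + 2 * np.pi * (r @ dk)
            M = _rotate_z(M, np.broadcast_to(ang, (n,)) if np.isscalar(ang) else ang)
    mxy = np.hypot(M[:, 0], M[:, 1])
    fa = np.degrees(np.arcsin(np.clip(mxy, 0.0, 1.0)))
    return FlipAngleMap(grid, grid.scatter(fa))
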
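"""Simultaneous <-> time-division-multiplexed pulse conversion and RF power
accounting.

Because coil and time-step indices enter the small-tip-angle sum
symmetrically, a pulse driving ``Nc`` coils simultaneously over ``Nt``
sub-pulses can be rearranged into a pulse driving ``Nc/G`` logical channels
over ``G*Nt`` sub-pulses that cycle through the ``G`` coil groups, with
k-space locations repeated ``G`` times. The excitation is unchanged (exactly,
when off-resonance is ignored), at the cost of either a ``G``-fold longer
pulse or a ``G``-fold higher average power (keep-duration mode: sub-pulse
durations divided by G, amplitudes multiplied by G).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import ChannelSchedule, PulseProgram, PulseTiming

__all__ = ["MultiplexMode", "PowerReport", "to_multiplexed", "merge_to_simultaneous", "average_power"]

DEFAULT_IMPEDANCE_OHM = 50.0


class MultiplexMode(enum.Enum):
    """How to handle the doubled number of sub-pulses when multiplexing."""

    KEEP_DURATION = "keep_duration"      # sub-pulse duration / G, amplitudes * G
    DOUBLE_DURATION = "double_duration"  # duration and amplitudes unchanged


@dataclass(frozen=True)
class PowerReport:
    """Time-averaged and peak instantaneous RF power into a reference
    impedance (all in watts; peak/average per channel plus totals)."""

    average_total_w: float
    average_per_channel_w: np.ndarray
    peak_per_channel_w: np.ndarray
    impedance_ohm: float = DEFAULT_IMPEDANCE_OHM

    @property
    def peak_w(self) -> float:
        return float(self.peak_per_channel_w.max())


def _row_groups(pulse: PulseProgram, rows: list[str] | None, groups: int) -> list[np.ndarray]:
    """Split the input pulse's coil axis into G contiguous groups."""
    nc = pulse.n_channels
    if nc % groups:
        raise ValueError(f"coil count {nc} not divisible into {groups} groups")
    m = nc // groups
    return [np.arange(g * m, (g + 1) * m) for g in range(groups)]


def to_multiplexed(
    pulse: PulseProgram,
    mode: MultiplexMode,
    group_labels: tuple[str, ...] = ("top", "bottom"),
) -> PulseProgram:
    """Rearrange a simultaneous pulse into its time-division-multiplexed form.

    The input must drive all coils simultaneously (static schedule) with a
    coil count divisible by the number of groups (default two equal rows,
    first half = first label). Output step ``tau*G + g`` carries the group-g
    columns of input step ``tau``; k-locations are repeated group-wise;
    switch gaps appear implicitly between sub-pulses whose routing differs.
    """
    g = len(group_labels)
    if g < 2:
        raise ValueError("need at least two groups")
    cm = pulse.schedule.coil_map
    if not all(np.array_equal(cm[0], cm[t]) for t in range(cm.shape[0])):
        raise ValueError("input pulse must not already switch its schedule")
    groups = _row_groups(pulse, None, g)
    m = pulse.n_channels // g
    nt = pulse.n_steps

    amp = np.empty((g * nt, m), dtype=complex)
    k = np.empty((g * nt, 3))
    for tau in range(nt):
        for gi in range(g):
            amp[tau * g + gi] = pulse.amplitudes[tau, groups[gi]]
            k[tau * g + gi] = pulse.k_locations[tau]

    if mode is MultiplexMode.KEEP_DURATION:
        amp *= g
        dt = pulse.timing.sub_pulse_duration / g
    else:
        dt = pulse.timing.sub_pulse_duration

    # logical channel c maps to physical coil of its live group
    group_maps = [cm[0][groups[gi]] for gi in range(g)]
    schedule = ChannelSchedule.cyclic(group_maps, g * nt, group_labels)
    timing = PulseTiming(
        sub_pulse_duration=dt,
        tr=pulse.timing.tr,
        switch_gap=pulse.timing.switch_gap,
        blip_duration=pulse.timing.blip_duration,
    )
    return PulseProgram(
        amp, k, timing, schedule,
        meta={**pulse.meta, "multiplex_mode": mode.value, "multiplex_groups": g},
    )


def merge_to_simultaneous(
    pulse: PulseProgram, mode: MultiplexMode | None = None
) -> PulseProgram:
    """Inverse rearrangement: recover the simultaneous pulse whose
    multiplexed form is the input.

    Requires a schedule that strictly cycles through G coil groups and
    group-wise repeated k-locations. The amplitude scaling to undo is taken
    from ``mode`` or, if omitted, from the ``multiplex_mode`` metadata
    stamped by :func:`to_multiplexed`.
    """
    if mode is None:
        tag = pulse.meta.get("multiplex_mode")
        if tag is None:
            raise ValueError("multiplex mode unknown; pass it explicitly")
        mode = MultiplexMode(tag)
    g = int(pulse.meta.get("multiplex_groups", 2))
    if pulse.n_steps % g:
        raise ValueError("step count not divisible by group count")
    nt = pulse.n_steps // g
    cm = pulse.schedule.coil_map
    for t in range(pulse.n_steps):
        if not np.array_equal(cm[t], cm[t % g]):
            raise ValueError("schedule does not strictly cycle through the groups")
    flat = np.concatenate([cm[gi] for gi in range(g)])
    if len(set(flat.tolist())) != flat.size:
        raise ValueError("schedule does not cycle through disjoint coil groups")
    for tau in range(nt):
        block = pulse.k_locations[tau * g:(tau + 1) * g]
        if not np.all(block == block[0]):
            raise ValueError("k-locations are not group-wise repeated")

    m = pulse.n_channels
    amp = np.empty((nt, g * m), dtype=complex)
    k = np.empty((nt, 3))
    coil_order = np.concatenate([cm[gi] for gi in range(g)])
    for tau in range(nt):
        for gi in range(g):
            amp[tau, gi * m:(gi + 1) * m] = pulse.amplitudes[tau * g + gi]
        k[tau] = pulse.k_locations[tau * g]

    if mode is MultiplexMode.KEEP_DURATION:
        amp /= g
        dt = pulse.timing.sub_pulse_duration * g
    else:
        dt = pulse.timing.sub_pulse_duration

    schedule = ChannelSchedule(np.tile(coil_order, (nt, 1)))
    timing = PulseTiming(
        sub_pulse_duration=dt,
        tr=pulse.timing.tr,
        switch_gap=pulse.timing.switch_gap,
        blip_duration=pulse.timing.blip_duration,
    )
    meta = {k_: v for k_, v in pulse.meta.items() if not k_.startswith("multiplex_")}
    return PulseProgram(amp, k, timing, schedule, meta=meta)


def average_power(pulse: PulseProgram, impedance_ohm: float = DEFAULT_IMPEDANCE_OHM) -> PowerReport:
    """RF power bookkeeping over one TR.

    Average power sums ``|p|^2 / Z * dt`` over sub-pulses and channels and
    divides by TR; switch gaps and gradient blips carry no RF and do not
    contribute. Peak instantaneous per-channel power is ``max_t |p|^2 / Z``.
    """
    if pulse.timing.tr <= 0:
        raise ValueError("TR must be positive")
    p2 = np.abs(pulse.amplitudes) ** 2 / impedance_ohm    # (nt, nch) watts
    dt = pulse.timing.sub_pulse_duration
    avg_per_ch = p2.sum(axis=0) * dt / pulse.timing.tr
    return PowerReport(
        average_total_w=float(avg_per_ch.sum()),
        average_per_channel_w=avg_per_ch,
        peak_per_channel_w=p2.max(axis=0),
        impedance_ohm=impedance_ohm,
    )
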
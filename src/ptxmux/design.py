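"""SAR-constrained magnitude-least-squares pulse design for static shims and
kT-points pulses, with L-curve sweeps and Pareto-front extraction.

The design problem is

    min_{P, K}  || |A(K) P| - b ||_2^2
    s.t.        (dt/TR) sum_j p_j^H V_n p_j <= lSARmax   for every VOP n

with P the stacked complex sub-pulse amplitudes, K the excitation k-space
locations (the last one pinned to k=0), b the uniform flip-angle target in
radians and V_n the VOP matrices. For multiplexed transmission consecutive
sub-pulse pairs share one k-location; this is enforced by parameterizing K
per pair rather than per step. The non-smooth magnitude is smoothed as
sqrt(|z|^2 + eps^2); analytic gradients are supplied throughout and can be
certified against finite differences with :func:`gradient_check`.

The trade-off between excitation fidelity and the local-SAR limit is
explored by the standard heuristic: a joint unconstrained (P, K) solve from
random initialization, followed by warm-started RF-only solves on a linearly
decreasing grid of SAR limits (an L-curve); the Pareto front over many
restarts approximates the achievable trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .core import (
    ChannelFieldSet,
    ChannelSchedule,
    CoilLabel,
    OffResonanceMap,
    PulseProgram,
    PulseTiming,
    SystemMatrix,
    build_system_matrix,
    nrmse,
    simulate_sta,
)
from .multiplex import MultiplexMode, to_multiplexed
from .sar import QMatrixSet, VOPSet, compress_vop, local_sar

__all__ = [
    "DesignProblem",
    "DesignSolution",
    "TradeoffCurve",
    "Scenario",
    "SCENARIO_DT_S",
    "design_pulse",
    "random_init",
    "lcurve",
    "pareto",
    "build_scenario",
    "make_problem",
    "evaluate_converted",
    "gradient_check",
]

# Sub-pulse durations per driving scenario (seconds).
SCENARIO_DT_S = {
    "top": 0.2e-3,
    "bottom": 0.2e-3,
    "full16": 0.2e-3,
    "multi8_conv": 0.1e-3,
    "multi8_opt": 0.1e-3,
    "multi8_2T_opt": 0.2e-3,
    "passive_split": 0.2e-3,
}

PAIR_PHASE_DEG = -22.5  # intra-pair phase of the passive splitter


@dataclass
class DesignProblem:
    """A fully specified pulse-design instance.

    ``schedule`` fixes the channel->coil assignment per sub-pulse;
    ``couple_pairs`` shares one k-location per consecutive step pair
    (multiplexed kT points). ``lsar_max`` of None means unconstrained.
    ``k_bounds_per_m`` is used both as the random-initialization range and
    as a box bound during optimization.
    """

    fields: ChannelFieldSet
    db0: OffResonanceMap
    schedule: ChannelSchedule
    timing: PulseTiming
    target_deg: float = 5.0
    vops: VOPSet | None = None
    lsar_max: float | None = None
    couple_pairs: bool = False
    optimize_k: bool = True
    k_bounds_per_m: float = 14.0
    k_groups_init: np.ndarray | None = None  # frozen k per group when optimize_k=False
    name: str = ""

    def __post_init__(self):
        if self.lsar_max is not None and self.lsar_max <= 0:
            raise ValueError("lSARmax must be positive (or None)")
        if self.couple_pairs and self.schedule.n_steps % 2:
            raise ValueError("paired k-locations need an even number of steps")
        self.schedule.validate_against(self.fields)
        if self.vops is not None and self.vops.nc != self.schedule.n_channels:
            raise ValueError("VOP dimension does not match channel count")

    @property
    def n_steps(self) -> int:
        return self.schedule.n_steps

    @property
    def n_channels(self) -> int:
        return self.schedule.n_channels

    @property
    def n_k_groups(self) -> int:
        """Independent k-locations (pairs collapse to one)."""
        return self.n_steps // 2 if self.couple_pairs else self.n_steps

    @property
    def n_free_k(self) -> int:
        """Optimized k-locations: the last (pair) is pinned to k = 0."""
        if not self.optimize_k:
            return 0
        return max(self.n_k_groups - 1, 0)

    def group_of_step(self) -> np.ndarray:
        steps = np.arange(self.n_steps)
        return steps // 2 if self.couple_pairs else steps

    def skeleton(self, k_groups: np.ndarray | None = None) -> PulseProgram:
        """Zero-amplitude pulse fixing timing/schedule/k structure. Distinct
        placeholder k's keep the gap rule (blip between k changes) aligned
        with the generic optimized pulse."""
        g = self.group_of_step()
        if k_groups is None:
            k_groups = np.zeros((self.n_k_groups, 3))
            for i in range(self.n_k_groups - 1):
                k_groups[i] = [float(i + 1), 0.0, 0.0]
        k = np.asarray(k_groups)[g]
        amp = np.zeros((self.n_steps, self.n_channels), dtype=complex)
        return PulseProgram(amp, k, self.timing, self.schedule)

    def system(self) -> SystemMatrix:
        return build_system_matrix(self.fields, self.db0, self.skeleton())


@dataclass
class DesignSolution:
    """Result of one design solve."""

    pulse: PulseProgram
    nrmse: float
    psar: float | None
    converged: bool
    objective_history: list[float] = field(default_factory=list)
    lsar_max: float | None = None
    message: str = ""


@dataclass
class TradeoffCurve:
    """Ordered (lSARmax, NRMSE) points from an L-curve sweep (lSARmax
    decreasing) or a Pareto front, with solution references and
    provenance."""

    lsar_max: np.ndarray
    nrmse: np.ndarray
    psar: np.ndarray
    solutions: list[DesignSolution]
    provenance: dict = field(default_factory=dict)
    kind: str = "sweep"

    def __post_init__(self):
        self.lsar_max = np.asarray(self.lsar_max, dtype=float)
        self.nrmse = np.asarray(self.nrmse, dtype=float)
        self.psar = np.asarray(self.psar, dtype=float)
        if self.kind == "sweep" and self.lsar_max.size > 1:
            if not np.all(np.diff(self.lsar_max) < 0):
                raise ValueError("sweep levels must be strictly decreasing")

    @property
    def min_nrmse(self) -> float:
        return float(self.nrmse.min())

    def __len__(self) -> int:
        return self.lsar_max.size


# ---------------------------------------------------------------------------
# objective / constraints


class _MLSObjective:
    """Smoothed magnitude-least-squares objective with analytic gradient
    over stacked variables [Re P, Im P, K_free]."""

    def __init__(self, problem: DesignProblem, sm: SystemMatrix | None = None):
        self.problem = problem
        sm = problem.system() if sm is None else sm
        self.sm = sm
        self.base = sm.base                      # (N, Nt, Nch)
        self.r = sm.positions                    # (N, 3)
        self.nt = problem.n_steps
        self.nch = problem.n_channels
        self.np_ = self.nt * self.nch
        self.b = np.deg2rad(problem.target_deg)
        self.eps = 1e-8 * self.b
        self.group = problem.group_of_step()
        self.nfree = problem.n_free_k

    def split(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = v[: self.np_]
        y = v[self.np_: 2 * self.np_]
        P = (x + 1j * y).reshape(self.nt, self.nch)
        kfree = v[2 * self.np_:].reshape(self.nfree, 3)
        return P, kfree

    def k_groups(self, kfree: np.ndarray) -> np.ndarray:
        if self.problem.k_groups_init is not None:
            kg = np.array(self.problem.k_groups_init, dtype=float)
        else:
            kg = np.zeros((self.problem.n_k_groups, 3))
        if self.nfree:
            kg[: self.nfree] = kfree
        return kg

    def k_steps(self, kfree: np.ndarray) -> np.ndarray:
        return self.k_groups(kfree)[self.group]

    def pack(self, P: np.ndarray, kfree: np.ndarray | None = None) -> np.ndarray:
        parts = [P.real.ravel(), P.imag.ravel()]
        if self.nfree:
            parts.append(np.zeros(3 * self.nfree) if kfree is None else np.asarray(kfree).ravel())
        return np.concatenate(parts)

    def _forward(self, P, kfree):
        E = np.exp(2j * np.pi * (self.r @ self.k_steps(kfree).T))   # (N, Nt)
        u = np.einsum("njc,jc->nj", self.base, P, optimize=True)    # (N, Nt)
        z = (E * u).sum(axis=1)
        m = np.sqrt(np.abs(z) ** 2 + self.eps**2)
        return E, u, z, m

    def value(self, v: np.ndarray) -> float:
        P, kfree = self.split(v)
        *_, m = self._forward(P, kfree)
        return float(np.sum((m - self.b) ** 2))

    def value_and_grad(self, v: np.ndarray) -> tuple[float, np.ndarray]:
        P, kfree = self.split(v)
        E, u, z, m = self._forward(P, kfree)
        f = float(np.sum((m - self.b) ** 2))
        w = (m - self.b) / m * z                                    # (N,)
        gP = np.einsum("njc,nj,n->jc", self.base.conj(), E.conj(), w, optimize=True)
        grads = [2 * gP.real.ravel(), 2 * gP.imag.ravel()]
        if self.nfree:
            s = np.imag(np.conj(w)[:, None] * E * u)                # (N, Nt)
            gk_steps = -4 * np.pi * np.einsum("nd,nj->jd", self.r, s, optimize=True)
            gk = np.zeros((self.problem.n_k_groups, 3))
            np.add.at(gk, self.group, gk_steps)
            grads.append(gk[: self.nfree].ravel())
        return f, np.concatenate(grads)

    def exact_nrmse(self, v: np.ndarray) -> float:
        P, kfree = self.split(v)
        *_, z, _ = self._forward(P, kfree)
        return float(np.sqrt(np.mean((np.abs(z) - self.b) ** 2)) / self.b)

    def solution_pulse(self, v: np.ndarray) -> PulseProgram:
        P, kfree = self.split(v)
        return PulseProgram(P, self.k_steps(kfree), self.problem.timing, self.problem.schedule)


class _SARConstraints:
    """Per-VOP quadratic SAR constraints g_n(P) = sar_n - lsar <= 0 with
    analytic jacobian (zero in the K block)."""

    def __init__(self, obj: _MLSObjective, vops: VOPSet, lsar: float):
        self.obj = obj
        self.V = vops.matrices
        self.lsar = lsar
        self.coef = obj.problem.timing.sub_pulse_duration / obj.problem.timing.tr

    def sar(self, v: np.ndarray) -> np.ndarray:
        P, _ = self.obj.split(v)
        return self.coef * np.einsum(
            "jc,ncd,jd->n", P.conj(), self.V, P, optimize=True
        ).real

    def fun(self, v: np.ndarray) -> np.ndarray:
        # SLSQP convention: feasible when >= 0
        return self.lsar - self.sar(v)

    def jac(self, v: np.ndarray) -> np.ndarray:
        P, _ = self.obj.split(v)
        Vp = np.einsum("ncd,jd->njc", self.V, P, optimize=True)     # (n, Nt, Nch)
        gx = 2 * self.coef * Vp.real.reshape(self.V.shape[0], -1)
        gy = 2 * self.coef * Vp.imag.reshape(self.V.shape[0], -1)
        gk = np.zeros((self.V.shape[0], 3 * self.obj.nfree))
        return -np.hstack([gx, gy, gk])


def _k_bounds(obj: _MLSObjective) -> list[tuple[float | None, float | None]]:
    kb = obj.problem.k_bounds_per_m
    return [(None, None)] * (2 * obj.np_) + [(-kb, kb)] * (3 * obj.nfree)


def design_pulse(
    problem: DesignProblem,
    init: tuple[np.ndarray, np.ndarray | None],
    maxiter: int = 3000,
) -> DesignSolution:
    """Solve one design instance from the given initialization.

    ``init`` is ``(P0, K0)`` with P0 complex (n_steps, n_channels) volts and
    K0 the free k-locations (n_free_k, 3) in 1/m (ignored when k is fixed).
    Unconstrained problems are solved jointly over (P, K) with L-BFGS-B;
    SAR-constrained problems with SLSQP using analytic jacobians. A
    terminal point violating a constraint by more than 1e-6 relative is
    rescaled to exact feasibility (amplitude shrink) and flagged.
    """
    obj = _MLSObjective(problem)
    P0, K0 = init
    P0 = np.asarray(P0, dtype=complex).reshape(problem.n_steps, problem.n_channels)
    v0 = obj.pack(P0, None if obj.nfree == 0 else K0)
    history: list[float] = []

    def f_and_g(v):
        f, g = obj.value_and_grad(v)
        history.append(f)
        return f, g

    if problem.lsar_max is None or problem.vops is None:
        res = optimize.minimize(
            f_and_g, v0, jac=True, method="L-BFGS-B",
            bounds=_k_bounds(obj) if obj.nfree else None,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                     "ftol": 1e-16, "gtol": 1e-12},
        )
        if obj.nfree:
            # block-coordinate polish: freeze K at its optimum and re-solve
            # the much better-conditioned RF-only subproblem to convergence
            P_j, k_j = obj.split(res.x)
            sub = DesignProblem(**{**problem.__dict__, "optimize_k": False,
                                   "k_groups_init": obj.k_groups(k_j)})
            sobj = _MLSObjective(sub)
            sres = optimize.minimize(
                sobj.value_and_grad, sobj.pack(P_j), jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                         "ftol": 1e-16, "gtol": 1e-12},
            )
            history.extend([float(sres.fun)])
            if sres.fun <= res.fun:
                P_s, _ = sobj.split(sres.x)
                res.x = obj.pack(P_s, k_j)
                res.fun = sres.fun
        converged = bool(res.success) or res.status == 1
    else:
        cons = _SARConstraints(obj, problem.vops, problem.lsar_max)
        res = optimize.minimize(
            f_and_g, v0, jac=True, method="SLSQP",
            bounds=_k_bounds(obj) if obj.nfree else None,
            constraints=[{"type": "ineq", "fun": cons.fun, "jac": cons.jac}],
            options={"maxiter": min(maxiter, 400), "ftol": 1e-10},
        )
        converged = bool(res.success)

    v = res.x
    pulse = obj.solution_pulse(v)
    psar = None
    message = str(res.message)
    if problem.vops is not None:
        psar = local_sar(pulse, problem.vops).psar
        if problem.lsar_max is not None and psar > problem.lsar_max * (1 + 1e-6):
            # feasibility rescale: SAR is quadratic in amplitude
            scale = np.sqrt(problem.lsar_max / psar) * (1 - 1e-12)
            pulse = PulseProgram(pulse.amplitudes * scale, pulse.k_locations,
                                 pulse.timing, pulse.schedule, meta=dict(pulse.meta))
            psar = local_sar(pulse, problem.vops).psar
            v = obj.pack(pulse.amplitudes, obj.split(v)[1] if obj.nfree else None)
            message += " [rescaled to feasibility]"
    return DesignSolution(
        pulse=pulse,
        nrmse=obj.exact_nrmse(v),
        psar=psar,
        converged=converged,
        objective_history=history,
        lsar_max=problem.lsar_max,
        message=message,
    )


def random_init(problem: DesignProblem, rng: np.random.Generator,
                p_std_v: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Random initialization: k uniform in the +-k_bounds box, pulse
    weights complex normal with the given standard deviation (volts)."""
    kb = problem.k_bounds_per_m
    K0 = rng.uniform(-kb, kb, size=(problem.n_free_k, 3))
    P0 = (rng.standard_normal((problem.n_steps, problem.n_channels))
          + 1j * rng.standard_normal((problem.n_steps, problem.n_channels))) * (p_std_v / np.sqrt(2))
    return P0, K0


def lcurve(
    problem: DesignProblem,
    seed: int,
    levels: int = 64,
    floor_w_kg: float = 0.1,
    maxiter: int = 3000,
) -> TradeoffCurve:
    """One L-curve: joint unconstrained solve from a seeded random start,
    then warm-started RF-only solves at linearly decreasing SAR limits.

    The unconstrained optimum (P_inf, K_inf) defines the first curve point
    (its own VOP pSAR as the level); the remaining ``levels - 1`` limits
    decrease linearly to ``floor_w_kg`` with K frozen at K_inf and P warm
    started from the previous level. Solver failures are recorded per level
    and the curve is still returned.
    """
    if problem.vops is None:
        raise ValueError("L-curve requires a VOP set for SAR evaluation")
    rng = np.random.default_rng(seed)
    P0, K0 = random_init(problem, rng)
    free = design_pulse(
        DesignProblem(**{**problem.__dict__, "lsar_max": None}),
        (P0, K0), maxiter=maxiter,
    )
    psar_inf = local_sar(free.pulse, problem.vops).psar
    free.psar = psar_inf

    if psar_inf <= floor_w_kg or levels < 2:
        return TradeoffCurve(
            np.array([psar_inf]), np.array([free.nrmse]), np.array([psar_inf]),
            [free], provenance={"seed": seed, "scenario": problem.name},
        )

    grid = np.linspace(psar_inf, floor_w_kg, levels)
    k_star = free.pulse.k_locations[:: 2 if problem.couple_pairs else 1].copy()

    lsar_list = [grid[0]]
    nrmse_list = [free.nrmse]
    psar_list = [psar_inf]
    sols = [free]
    P_warm = free.pulse.amplitudes
    for lev in grid[1:]:
        sub = DesignProblem(**{**problem.__dict__, "lsar_max": float(lev),
                               "optimize_k": False, "k_groups_init": k_star})
        sol = design_pulse(sub, (P_warm, None), maxiter=maxiter)
        lsar_list.append(float(lev))
        nrmse_list.append(sol.nrmse)
        psar_list.append(sol.psar)
        sols.append(sol)
        P_warm = sol.pulse.amplitudes

    # Backward warm-start pass: a solution found at a tighter SAR limit is
    # feasible at every looser one, so whenever it beats a looser level's
    # solution, re-solve that level from it and keep the better of the two.
    # This removes warm-start artifacts and makes the curve monotone.
    for i in range(len(sols) - 2, -1, -1):
        if nrmse_list[i] <= nrmse_list[i + 1]:
            continue
        tighter = sols[i + 1]
        if i == 0:
            cand = tighter  # unconstrained endpoint adopts the better point
        else:
            sub = DesignProblem(**{**problem.__dict__, "lsar_max": lsar_list[i],
                                   "optimize_k": False, "k_groups_init": k_star})
            cand = design_pulse(sub, (tighter.pulse.amplitudes, None),
                                maxiter=maxiter)
            if cand.nrmse > tighter.nrmse:
                cand = tighter
        if cand.nrmse < nrmse_list[i]:
            sols[i] = cand
            nrmse_list[i] = cand.nrmse
            psar_list[i] = cand.psar
    return TradeoffCurve(
        np.array(lsar_list), np.array(nrmse_list), np.array(psar_list), sols,
        provenance={"seed": seed, "scenario": problem.name,
                    "levels": levels, "floor_w_kg": floor_w_kg},
    )


def pareto(curves: Sequence[TradeoffCurve]) -> TradeoffCurve:
    """Non-dominated subset of all (pSAR, NRMSE) points across curves.

    A point is dominated if another point has both lower-or-equal pSAR and
    lower-or-equal NRMSE (strictly lower in at least one). The front is
    returned with pSAR decreasing (NRMSE non-decreasing along it)."""
    pts: list[tuple[float, float, DesignSolution, float]] = []
    for c in curves:
        for i in range(len(c)):
            pts.append((float(c.psar[i]), float(c.nrmse[i]), c.solutions[i],
                        float(c.lsar_max[i])))
    if not pts:
        return TradeoffCurve(np.empty(0), np.empty(0), np.empty(0), [], kind="pareto")
    pts.sort(key=lambda t: (t[0], t[1]))
    front: list[tuple[float, float, DesignSolution, float]] = []
    best = np.inf
    for p in pts:
        if p[1] < best:
            front.append(p)
            best = p[1]
    front = front[::-1]  # pSAR decreasing
    return TradeoffCurve(
        np.array([p[3] for p in front]),
        np.array([p[1] for p in front]),
        np.array([p[0] for p in front]),
        [p[2] for p in front],
        kind="pareto",
    )


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Scenario:
    """Effective channel set, schedule structure, SAR operators and
    sub-pulse duration for one driving scenario."""

    name: str
    fields: ChannelFieldSet
    vops: VOPSet
    dt_s: float
    multiplexed: bool = False
    group_maps: list[np.ndarray] | None = None
    group_labels: tuple[str, ...] | None = None
    coupling: np.ndarray | None = None

    def schedule_for(self, n_kt: int) -> tuple[ChannelSchedule, bool]:
        """Schedule and pair-coupling flag for an ``n_kt``-point design
        (n_kt = 1 is a static shim)."""
        if self.multiplexed:
            sched = ChannelSchedule.cyclic(self.group_maps, 2 * n_kt, self.group_labels)
            return sched, True
        nch = self.fields.n_coils
        return ChannelSchedule.static(nch, n_kt), False


def passive_split_coupling(fields16: ChannelFieldSet) -> np.ndarray:
    """8x16 coupling matrix pairing each top-row element with the matching
    bottom-row element at a fixed -22.5 deg intra-pair phase (static power
    splitters and phase shifters)."""
    top = fields16.row_indices("top")
    bottom = fields16.row_indices("bottom")
    if top.size != bottom.size:
        raise ValueError("rows of unequal size")
    C = np.zeros((top.size, fields16.n_coils), dtype=complex)
    shift = np.exp(1j * np.deg2rad(PAIR_PHASE_DEG))
    for m in range(top.size):
        C[m, top[m]] = 1.0
        C[m, bottom[m]] = shift
    return C


def build_scenario(
    name: str,
    fields16: ChannelFieldSet,
    qsets: dict,
    vop_overestimation: float = 0.05,
) -> Scenario:
    """Assemble the effective field set, schedule structure and VOP set for
    a named driving scenario.

    ``qsets`` maps names to SAR operators: precompressed VOP sets under
    ``"top_vop"``, ``"bottom_vop"``, ``"full_vop"``, ``"combined_vop"``;
    for ``passive_split`` a raw ``"full"`` QMatrixSet from which the
    coupling-conjugated effective set is compressed (or a precompressed
    ``"passive_split_vop"``).
    """
    if name not in SCENARIO_DT_S:
        raise ValueError(f"unknown scenario {name!r}")
    dt = SCENARIO_DT_S[name]

    if name in ("top", "bottom"):
        idx = fields16.row_indices(name)
        vop = qsets[f"{name}_vop"]
        sub = fields16.subset(idx)
        if vop.nc != sub.n_coils:
            raise ValueError("VOP dimension does not match the row subset")
        return Scenario(name, sub, vop, dt)
    if name == "full16":
        return Scenario(name, fields16, qsets["full_vop"], dt)
    if name in ("multi8_opt", "multi8_2T_opt", "multi8_conv"):
        top = fields16.row_indices("top")
        bottom = fields16.row_indices("bottom")
        if top.size != bottom.size:
            raise ValueError("rows of unequal size")
        return Scenario(
            name, fields16, qsets["combined_vop"], dt, multiplexed=True,
            group_maps=[top, bottom], group_labels=("top", "bottom"),
        )
    # passive_split
    C = passive_split_coupling(fields16)
    beta = fields16.sensitivities.reshape(fields16.n_coils, -1)
    eff = (C @ beta).reshape((C.shape[0],) + fields16.grid.shape)
    top_idx = fields16.row_indices("top")
    bottom_idx = fields16.row_indices("bottom")
    labels = [
        # midpoint azimuth of the pair keeps the CP-mode convention meaningful
        CoilLabel("pair", m + 1,
                  0.5 * (fields16.labels[top_idx[m]].azimuth_deg
                         + fields16.labels[bottom_idx[m]].azimuth_deg))
        for m in range(C.shape[0])
    ]
    eff_fields = ChannelFieldSet(fields16.grid, eff, labels)
    if "passive_split_vop" in qsets:
        vop = qsets["passive_split_vop"]
    else:
        qfull: QMatrixSet = qsets["full"]
        qeff = np.einsum("mc,vcd,nd->vmn", C.conj(), qfull.matrices, C, optimize=True)
        qeff = 0.5 * (qeff + qeff.conj().transpose(0, 2, 1))
        vop = compress_vop(QMatrixSet(qeff, qfull.voxel_ids,
                                      np.array(["passive_split"] * qfull.n_voxels)),
                           vop_overestimation, probe_modes=0)
    return Scenario(name, eff_fields, vop, dt, coupling=C)


def make_problem(
    scenario: Scenario,
    db0: OffResonanceMap,
    n_kt: int,
    tr_s: float = 10e-3,
    target_deg: float = 5.0,
    lsar_max: float | None = None,
    k_bounds_per_m: float = 14.0,
) -> DesignProblem:
    """Design problem for ``n_kt`` kT points under a scenario (n_kt = 1 is a
    static shim with k fixed at the origin)."""
    schedule, couple = scenario.schedule_for(n_kt)
    timing = PulseTiming(sub_pulse_duration=scenario.dt_s, tr=tr_s)
    return DesignProblem(
        fields=scenario.fields,
        db0=db0,
        schedule=schedule,
        timing=timing,
        target_deg=target_deg,
        vops=scenario.vops,
        lsar_max=lsar_max,
        couple_pairs=couple,
        optimize_k=n_kt > 1,
        k_bounds_per_m=k_bounds_per_m,
        name=scenario.name,
    )


def evaluate_converted(
    full16_solution: DesignSolution,
    fields16: ChannelFieldSet,
    db0: OffResonanceMap,
    combined_vop: VOPSet,
    target_deg: float = 5.0,
) -> DesignSolution:
    """The "convert without re-optimization" scenario: rearrange an
    optimized simultaneous pulse into duration-preserving multiplexed form
    and evaluate (never re-optimize) its flip-angle error and its pSAR under
    the jointly compressed VOPs."""
    mux = to_multiplexed(full16_solution.pulse, MultiplexMode.KEEP_DURATION)
    A = build_system_matrix(fields16, db0, mux)
    fa = simulate_sta(A, mux)
    return DesignSolution(
        pulse=mux,
        nrmse=nrmse(fa, target_deg),
        psar=local_sar(mux, combined_vop).psar,
        converged=full16_solution.converged,
        lsar_max=None,
        message="converted from full16",
    )


def gradient_check(
    problem: DesignProblem,
    point: tuple[np.ndarray, np.ndarray | None] | None = None,
    step: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> dict:
    """Certify the analytic gradients against central finite differences.

    Checks the MLS objective gradient (w.r.t. real/imag P and the free
    k-locations) and every SAR-constraint gradient at an interior point.
    Reports the worst relative component error, normalized by the inf-norm
    of the finite-difference gradient.
    """
    obj = _MLSObjective(problem)
    if point is None:
        rng = np.random.default_rng(0) if rng is None else rng
        P0, K0 = random_init(problem, rng)
        point = (P0, K0)
    P0, K0 = point
    v = obj.pack(np.asarray(P0, dtype=complex), K0 if obj.nfree else None)

    def fd_grad(fun, v):
        g = np.empty_like(v)
        for i in range(v.size):
            vp, vm = v.copy(), v.copy()
            h = step * max(1.0, abs(v[i]))
            vp[i] += h
            vm[i] -= h
            g[i] = (fun(vp) - fun(vm)) / (2 * h)
        return g

    _, g_ana = obj.value_and_grad(v)
    g_fd = fd_grad(obj.value, v)
    scale = max(np.abs(g_fd).max(), 1e-300)
    report = {
        "objective_rel_err": float(np.abs(g_ana - g_fd).max() / scale),
        "objective_worst_component": int(np.argmax(np.abs(g_ana - g_fd))),
        "constraints_rel_err": [],
    }
    if problem.vops is not None:
        cons = _SARConstraints(obj, problem.vops, problem.lsar_max or 1.0)
        jac = cons.jac(v)
        for n in range(min(problem.vops.n_vops, 8)):  # spot-check a few VOPs
            gfd = fd_grad(lambda vv, n=n: cons.fun(vv)[n], v)
            sc = max(np.abs(gfd).max(), 1e-300)
            report["constraints_rel_err"].append(float(np.abs(jac[n] - gfd).max() / sc))
    report["max_rel_err"] = float(max([report["objective_rel_err"]]
                                      + report["constraints_rel_err"]))
    return report
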
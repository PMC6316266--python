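"""Continuum-damage pitting-corrosion engine.

Each element carries a scalar damage parameter ``dP`` in [0, 1] that grows
at the rate

    d(dP)/dt = (delta_u / Le) * Ku * lambda_p            [1/h]

where ``Ku`` (1/h) is the kinetic constant of the underlying uniform
corrosion process, ``delta_u`` and ``Le`` (mm) are the material and element
characteristic lengths, and ``lambda_p`` is an element-specific
dimensionless pitting multiplier.  ``lambda_p`` is drawn from a Weibull
distribution (shape ``gamma``, scale ``psi``) on the initially exposed
surface; when an element reaches ``dP = 1`` it is removed from the mesh and
its face neighbours inherit ``lambda_p' = beta * lambda_p``, which is what
lets a pit accelerate as it burrows.  ``mode="uniform"`` pins
``lambda_p = 1`` everywhere, recovering homogeneous surface recession.

Times are hours throughout; day-based interfaces convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import VoxelMesh, exposed_elements

__all__ = [
    "PitParams",
    "SimState",
    "MassLossCurve",
    "INTERIOR",
    "EXPOSED",
    "REMOVED",
    "NonTerminationError",
    "weibull_pdf",
    "weibull_interval_prob",
    "sample_lambda",
    "init_state",
    "damage_increment",
    "remove_and_inherit",
    "compute_mass_loss",
    "simulate",
]

INTERIOR, EXPOSED, REMOVED = 0, 1, 2

#: Inherited lambda_p values are clipped here.  A long removal cascade with
#: beta > 1 multiplies lambda_p geometrically and would overflow; beyond the
#: cap an element's remaining lifetime is < 1e-10 h, far below any recorded
#: time resolution, so clipping is observationally neutral.
LAMBDA_CAP = 1e12

#: Per-step damage increment of the fastest active element (explicit Euler
#: step-size rule dt = _DP_CAP * Le / (delta_u * Ku * max active lambda_p)).
_DP_CAP = 0.1

#: Removal threshold: accumulated float steps summing to nominal 1.0 can
#: land at 1 - O(eps), so full damage is detected with a small tolerance.
_DP_FULL = 1.0 - 1e-9


class NonTerminationError(RuntimeError):
    """A mass-loss-target run that provably cannot reach its target."""


@dataclass(frozen=True)
class PitParams:
    """Constants of the pitting-corrosion model.

    Parameters
    ----------
    gamma, psi : float
        Weibull shape and scale of the pitting-parameter distribution
        (both dimensionless, > 0).
    beta : float
        Inheritance scale, ``lambda_p' = beta * lambda_p`` (>= 0).
    Ku : float
        Kinetic parameter of the uniform corrosion process (1/h, >= 0).
    delta_u : float or None
        Material characteristic length (mm).  ``None`` means
        ``delta_u = Le`` so the rate law reduces to ``Ku * lambda_p``.
    Le : float or None
        Element characteristic length (mm); ``None`` defers to the mesh.
    seed : int
        Seed of the single generator used for the surface lambda_p draws.
    mode : {"pitting", "uniform"}
        ``"uniform"`` forces ``lambda_p = 1`` everywhere.
    """

    gamma: float
    psi: float
    beta: float
    Ku: float
    delta_u: float | None = None
    Le: float | None = None
    seed: int = 0
    mode: str = "pitting"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.psi > 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.Ku < 0:
            raise ValueError(f"Ku must be >= 0, got {self.Ku}")
        if self.delta_u is not None and not self.delta_u > 0:
            raise ValueError(f"delta_u must be > 0, got {self.delta_u}")
        if self.Le is not None and not self.Le > 0:
            raise ValueError(f"Le must be > 0, got {self.Le}")
        if self.mode not in ("pitting", "uniform"):
            raise ValueError(f"mode must be 'pitting' or 'uniform', got {self.mode!r}")

    def bind(self, mesh: VoxelMesh) -> "PitParams":
        """Copy with ``Le`` (and, implicitly, ``delta_u``) tied to a mesh."""
        if self.Le is not None and not math.isclose(self.Le, mesh.Le):
            raise ValueError(f"params.Le={self.Le} conflicts with mesh.Le={mesh.Le}")
        return replace(self, Le=mesh.Le)

    @property
    def rate_scale(self) -> float:
        """``delta_u / Le`` with the ``delta_u = Le`` default (-> 1)."""
        if self.delta_u is None:
            return 1.0
        if self.Le is None:
            raise ValueError("delta_u given but Le unset; bind() to a mesh first")
        return self.delta_u / self.Le

    def damage_rate(self, lam: np.ndarray | float) -> np.ndarray | float:
        """d(dP)/dt in 1/h for pitting parameter(s) ``lam``."""
        return self.rate_scale * self.Ku * lam


@dataclass
class SimState:
    """Per-element simulation state: damage, pitting parameter, status."""

    dP: np.ndarray
    lambda_p: np.ndarray  # NaN = not yet assigned
    status: np.ndarray  # int8: INTERIOR / EXPOSED / REMOVED
    time: float = 0.0  # elapsed hours

    @property
    def n_elements(self) -> int:
        return self.dP.shape[0]

    def copy(self) -> "SimState":
        return SimState(self.dP.copy(), self.lambda_p.copy(), self.status.copy(), self.time)


@dataclass
class MassLossCurve:
    """Mass loss (%) over time (h), optionally with dimensionless time."""

    times_h: np.ndarray
    mass_loss_pct: np.ndarray
    dimensionless_time: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mass_loss_pct = np.asarray(self.mass_loss_pct, dtype=float)
        if self.times_h.shape != self.mass_loss_pct.shape:
            raise ValueError("times and mass_loss_pct must have equal length")
        if np.any(np.diff(self.mass_loss_pct) < -1e-9):
            raise ValueError("mass loss must be non-decreasing")
        if np.any((self.mass_loss_pct < -1e-9) | (self.mass_loss_pct > 100 + 1e-9)):
            raise ValueError("mass loss must lie in [0, 100]")

    @property
    def times_days(self) -> np.ndarray:
        return self.times_h / 24.0

    def final_time_for(self, mass_loss_pct: float) -> float:
        """First time (h) at which the curve reaches ``mass_loss_pct``."""
        m, t = self.mass_loss_pct, self.times_h
        if m[-1] < mass_loss_pct:
            raise ValueError(
                f"curve tops out at {m[-1]:.4g}% < requested {mass_loss_pct}%"
            )
        i = int(np.searchsorted(m, mass_loss_pct))
        if i == 0 or m[i] == m[i - 1]:
            return float(t[i])
        # linear interpolation inside the bracketing step
        w = (mass_loss_pct - m[i - 1]) / (m[i] - m[i - 1])
        return float(t[i - 1] + w * (t[i] - t[i - 1]))

    def interp(self, tau: np.ndarray) -> np.ndarray:
        """Mass loss at dimensionless times ``tau`` (requires alignment)."""
        if self.dimensionless_time is None:
            raise ValueError("curve has no dimensionless_time; align it first")
        return np.interp(tau, self.dimensionless_time, self.mass_loss_pct)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.times_h,
                "time_days": self.times_days,
                "mass_loss_pct": self.mass_loss_pct,
            }
        )
        if self.dimensionless_time is not None:
            df.insert(2, "dimensionless_time", self.dimensionless_time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Weibull pitting-parameter distribution


def weibull_pdf(x, gamma: float, psi: float):
    """Density of the pitting-parameter distribution.

    ``f(x) = (gamma/psi) (x/psi)^(gamma-1) exp(-(x/psi)^gamma)`` for
    ``x >= 0`` and 0 below.  Scalar in, scalar out.
    """
    if not (gamma > 0 and psi > 0):
        raise ValueError("gamma and psi must be > 0")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    with np.errstate(divide="ignore", over="ignore"):
        z = x[pos] / psi
        out[pos] = (gamma / psi) * z ** (gamma - 1.0) * np.exp(-(z**gamma))
    at0 = x == 0
    if at0.any():
        out[at0] = 1.0 / psi if gamma == 1 else (np.inf if gamma < 1 else 0.0)
    return out if out.ndim else float(out)


def weibull_interval_prob(a: float, b: float, gamma: float, psi: float) -> float:
    """P(a <= lambda_p <= b) from the closed-form CDF difference."""
    if not (gamma > 0 and psi > 0):
        raise ValueError("gamma and psi must be > 0")
    if a > b:
        raise ValueError(f"need a <= b, got a={a}, b={b}")
    lo, hi = max(a, 0.0), max(b, 0.0)

    def sf(x: float) -> float:
        return float(np.exp(-((x / psi) ** gamma))) if np.isfinite(x) else 0.0

    return sf(lo) - sf(hi)


def sample_lambda(n: int, params: PitParams, rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. pitting parameters via the inverse CDF.

    ``lambda = psi * (-ln U)^(1/gamma)`` with ``U ~ Uniform(0, 1)``; a fixed
    generator state reproduces the draws bit-for-bit.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    u = rng.random(n)
    # guard the measure-zero U == 0 draw
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return params.psi * (-np.log(u)) ** (1.0 / params.gamma)


# ---------------------------------------------------------------------------
# State evolution


def init_state(
    mesh: VoxelMesh,
    params: PitParams,
    rng: np.random.Generator | None = None,
    exposed: np.ndarray | None = None,
) -> SimState:
    """Fresh state: zero damage, pitting parameters on the exposed surface.

    ``exposed`` overrides the default initial surface (all boundary-flagged
    elements), e.g. to mask faces in front-speed experiments.  One Weibull
    draw is consumed per exposed element, in mesh-index order.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = mesh.n_elements
    dP = np.zeros(n)
    lam = np.full(n, np.nan)
    status = np.full(n, INTERIOR, dtype=np.int8)
    idx = np.flatnonzero(mesh.boundary) if exposed is None else np.sort(np.asarray(exposed))
    status[idx] = EXPOSED
    if params.mode == "uniform":
        lam[idx] = 1.0
    else:
        lam[idx] = sample_lambda(idx.size, params, rng)
    return SimState(dP, lam, status, 0.0)


def damage_increment(
    state: SimState, params: PitParams, dt: float, copy: bool = True
) -> SimState:
    """Advance damage of exposed elements by ``dt`` hours (explicit Euler).

    ``dP <- min(1, dP + (delta_u/Le) * Ku * lambda_p * dt)``; interior and
    removed elements are untouched; the clock advances by ``dt``.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if copy:
        state = state.copy()
    active = state.status == EXPOSED
    state.dP[active] = np.minimum(
        1.0, state.dP[active] + params.damage_rate(state.lambda_p[active]) * dt
    )
    state.time += dt
    return state


def remove_and_inherit(
    state: SimState,
    mesh: VoxelMesh,
    params: PitParams,
    rng: np.random.Generator | None = None,
    copy: bool = True,
) -> SimState:
    """Remove fully damaged elements; neighbours inherit beta * lambda_p.

    Every exposed element with ``dP >= 1`` becomes removed.  Each of its
    non-removed face neighbours becomes exposed and takes
    ``lambda_p' = max(current lambda_p, beta * max over donors)`` — the
    deterministic, order-independent resolution of competing donors.  In
    uniform mode inherited values are pinned to 1.  ``rng`` is accepted for
    interface symmetry but no randomness is consumed.
    """
    if state.n_elements != mesh.n_elements:
        raise ValueError("state does not match mesh size")
    if copy:
        state = state.copy()
    dying = np.flatnonzero((state.status == EXPOSED) & (state.dP >= _DP_FULL))
    if dying.size == 0:
        return state
    state.status[dying] = REMOVED
    state.dP[dying] = 1.0

    nb = mesh.neighbors[dying]  # (n_dying, 6)
    donor_lam = np.repeat(state.lambda_p[dying], 6)
    flat = nb.ravel()
    ok = (flat >= 0)
    targets = flat[ok]
    alive = state.status[targets] != REMOVED
    targets, gifts = targets[alive], params.beta * donor_lam[ok][alive]
    if targets.size:
        if params.mode == "uniform":
            gifts = np.ones_like(gifts)
        inherited = np.full(state.n_elements, -np.inf)
        np.maximum.at(inherited, targets, gifts)
        cur = np.where(np.isnan(state.lambda_p), -np.inf, state.lambda_p)
        newlam = np.maximum(cur, np.minimum(inherited, LAMBDA_CAP))
        touched = np.unique(targets)
        state.lambda_p[touched] = newlam[touched]
        state.status[touched] = EXPOSED
    return state


def compute_mass_loss(
    state: SimState, mesh: VoxelMesh, accounting: str = "partial"
) -> float:
    """Mass loss percentage of the coupon.

    ``"removed_only"`` counts deleted elements; ``"partial"`` credits the
    accumulated damage of still-standing elements too (``sum dP * V / V_tot``,
    removed elements contributing ``dP = 1``).  Both agree in the limit of
    instantaneous removal; ``partial`` gives smooth curves on coarse meshes.
    """
    if state.n_elements != mesh.n_elements:
        raise ValueError("state does not match mesh size")
    n = state.n_elements
    if accounting == "removed_only":
        return 100.0 * float((state.status == REMOVED).sum()) / n
    if accounting == "partial":
        return 100.0 * float(state.dP.sum()) / n
    raise ValueError(f"unknown accounting {accounting!r}")


# ---------------------------------------------------------------------------
# Time integration


def simulate(
    mesh: VoxelMesh,
    params: PitParams,
    t_end: float | None = None,
    mass_loss_target: float | None = None,
    record_times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    exposed: np.ndarray | None = None,
    accounting: str = "partial",
    snapshot_dir=None,
    keep_removed_in_snapshots: bool = False,
    max_steps: int = 5_000_000,
) -> MassLossCurve:
    """Run the corrosion simulation and return the mass-loss curve.

    Alternates explicit-Euler damage increments with removal/inheritance
    sweeps (operator splitting).  The step is adaptive,
    ``dt = 0.1 * Le / (delta_u * Ku * max active lambda_p)``, capping the
    fastest element's per-step damage gain at 0.1; it shrinks while a
    cascade is burning and recovers once the fast elements are gone.  The
    clock lands exactly on every requested ``record_time`` (hours) and on
    ``t_end``.

    Exactly one stopping rule is required: ``t_end`` (hours) or
    ``mass_loss_target`` (percent).  With a fixed ``params.seed`` (or an
    explicitly passed ``rng``) the whole trajectory is reproducible.

    When ``snapshot_dir`` is given, a VTK snapshot is written at each record
    time (``snapshot_d{days:g}.vtk``).
    """
    from .mesh import write_field_snapshot

    if (t_end is None) == (mass_loss_target is None):
        raise ValueError("give exactly one of t_end or mass_loss_target")
    if mass_loss_target is not None and not (0 < mass_loss_target <= 100):
        raise ValueError(f"mass_loss_target must be in (0, 100], got {mass_loss_target}")
    params = params.bind(mesh)
    state = init_state(mesh, params, rng=rng, exposed=exposed)

    if mass_loss_target is not None:
        active0 = state.status == EXPOSED
        if params.Ku == 0.0 or not np.any(state.lambda_p[active0] > 0):
            raise NonTerminationError(
                "Ku * max(lambda_p) == 0: the mass-loss target is unreachable"
            )

    rec = sorted(float(t) for t in record_times) if record_times is not None else []
    if rec and t_end is not None and rec[-1] > t_end + 1e-12:
        raise ValueError(f"record time {rec[-1]} h lies beyond t_end={t_end} h")
    rec_iter = iter(rec)
    next_rec = next(rec_iter, None)

    times = [0.0]
    losses = [compute_mass_loss(state, mesh, accounting)]

    def snap() -> None:
        if snapshot_dir is not None:
            days = state.time / 24.0
            path = f"{snapshot_dir}/snapshot_d{days:g}.vtk"
            write_field_snapshot(mesh, state, path, keep_removed=keep_removed_in_snapshots)

    if next_rec is not None and next_rec == 0.0:
        snap()
        next_rec = next(rec_iter, None)

    for _ in range(max_steps):
        active = state.status == EXPOSED
        rates = params.damage_rate(np.where(active, state.lambda_p, 0.0))
        max_rate = float(np.max(rates)) if rates.size else 0.0

        if max_rate <= 0.0:
            # nothing can evolve: flush remaining record times and finish
            if mass_loss_target is not None and losses[-1] < mass_loss_target - 1e-12:
                raise NonTerminationError(
                    "corrosion stalled (no active element with lambda_p > 0) "
                    f"at {losses[-1]:.4g}% < target {mass_loss_target}%"
                )
            while next_rec is not None:
                state.time = next_rec
                times.append(state.time)
                losses.append(losses[-1])
                snap()
                next_rec = next(rec_iter, None)
            if t_end is not None and state.time < t_end:
                state.time = t_end
                times.append(t_end)
                losses.append(losses[-1])
            break

        dt = _DP_CAP / max_rate
        if next_rec is not None:
            dt = min(dt, next_rec - state.time)
        if t_end is not None:
            dt = min(dt, t_end - state.time)
        dt = max(dt, 0.0)
        if dt > 0.0:
            state = damage_increment(state, params, dt, copy=False)
        state = remove_and_inherit(state, mesh, params, copy=False)
        times.append(state.time)
        losses.append(compute_mass_loss(state, mesh, accounting))

        if next_rec is not None and state.time >= next_rec - 1e-12:
            snap()
            next_rec = next(rec_iter, None)
        if mass_loss_target is not None and losses[-1] >= mass_loss_target:
            break
        if t_end is not None and state.time >= t_end and next_rec is None:
            break
    else:
        raise RuntimeError(f"simulation exceeded max_steps={max_steps}")

    curve = MassLossCurve(np.asarray(times), np.maximum.accumulate(losses))
    curve._final_state = state  # stash for callers that want the field
    return curve
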
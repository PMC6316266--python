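"""Immersion mass-loss data: units, the packaged Mg-Zn-Ca dataset,
dimensionless-time alignment and a pseudo-experiment generator.

Gravimetric immersion testing reports either mass loss per exposed area
(mg/cm^2) or, once normalized by the initial coupon mass, a percentage.  The
packaged Mg-1.2Zn-0.5Ca dataset (simulated body fluid, 37 C, pH 7.3-7.8,
n = 7 coupons, 28 days) is expressed in percent, and percent is the variable
every comparison in this package uses.

Because absolute corrosion rates are material constants we calibrate, the
curve comparison happens on a dimensionless time axis: tau = t / t_final,
where t_final is the last recorded time for an experiment and the first
time the simulated mass loss reaches the experimental final value for a
simulation.  That anchoring mirrors the run-until-target stopping rule used
in calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .mesh import VoxelMesh, build_coupon_mesh
from .model import MassLossCurve, PitParams, simulate

__all__ = [
    "ImmersionDataset",
    "mass_loss_per_area",
    "builtin_mgznca_dataset",
    "to_dimensionless",
    "synth_experiment",
]


@dataclass
class ImmersionDataset:
    """A measured (or pseudo-measured) mass-loss time series.

    ``times_days`` must be strictly increasing and start at 0 with
    ``mass_loss_pct[0] == 0``; values live in [0, 100].
    """

    times_days: np.ndarray
    mass_loss_pct: np.ndarray
    n_samples: int = 1
    label: str = ""
    dimensionless_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.mass_loss_pct = np.asarray(self.mass_loss_pct, dtype=float)
        if self.times_days.shape != self.mass_loss_pct.shape or self.times_days.size == 0:
            raise ValueError("times and mass loss must be equal-length, non-empty")
        if self.times_days[0] != 0 or self.mass_loss_pct[0] != 0:
            raise ValueError("dataset must start at (0 days, 0 %)")
        if np.any(np.diff(self.times_days) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.mass_loss_pct < 0) | (self.mass_loss_pct > 100)):
            raise ValueError("mass loss must lie in [0, 100]")

    @property
    def times_h(self) -> np.ndarray:
        return self.times_days * 24.0

    @property
    def final_mass_loss(self) -> float:
        return float(self.mass_loss_pct[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.times_days, "mass_loss_pct": self.mass_loss_pct}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_samples: int = 1, label: str = "") -> "ImmersionDataset":
        df = pd.read_csv(path)
        missing = {"time_days", "mass_loss_pct"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV lacks required column(s): {sorted(missing)}")
        return cls(
            df["time_days"].to_numpy(),
            df["mass_loss_pct"].to_numpy(),
            n_samples=n_samples,
            label=label,
        )


def mass_loss_per_area(mi: float, mf: float, A: float) -> float:
    """Gravimetric mass loss (mi - mf) / A in mg/cm^2.

    ``mi``/``mf`` are the coupon masses (mg) before and after immersion and
    cleaning; ``A`` is the exposed surface area (cm^2).  A final mass above
    the initial one (corrosion-product gain on a poorly cleaned coupon)
    triggers a warning but the negative value is still returned.
    """
    if not A > 0:
        raise ValueError(f"area must be > 0, got {A}")
    if mi < 0 or mf < 0:
        raise ValueError("masses must be non-negative")
    if mf > mi:
        warnings.warn(
            f"final mass {mf} mg exceeds initial {mi} mg (corrosion-product "
            "gain); returning a negative mass loss",
            stacklevel=2,
        )
    return (mi - mf) / A


def builtin_mgznca_dataset() -> ImmersionDataset:
    """The packaged Mg-1.2Zn-0.5Ca immersion dataset (SBF, 37 C, 28 days)."""
    path = resources.files("pitcorr") / "datasets" / "mgznca_sbf_37c.csv"
    with resources.as_file(path) as p:
        ds = ImmersionDataset.from_csv(p, n_samples=7, label="Mg-1.2Zn-0.5Ca SBF 37C")
    return ds


def to_dimensionless(obj, anchor_mass_loss: float | None = None):
    """Attach a dimensionless time axis tau = t / t_final.

    For an :class:`ImmersionDataset`, t_final is the last recorded time.
    For a simulated :class:`MassLossCurve`, t_final is the first time the
    curve reaches ``anchor_mass_loss`` (typically the experimental final
    mass loss); without an anchor the curve's last time is used.  Idempotent:
    re-aligning with the same anchor leaves tau unchanged.
    """
    if isinstance(obj, ImmersionDataset):
        t_final = obj.times_days[-1]
        if not (t_final > 0 and obj.final_mass_loss > 0):
            raise ValueError("dataset has no positive duration/mass loss to scale by")
        return replace(obj, dimensionless_time=obj.times_days / t_final)
    if isinstance(obj, MassLossCurve):
        if obj.times_h[-1] <= 0 or obj.mass_loss_pct[-1] <= 0:
            raise ValueError("curve has no positive duration/mass loss to scale by")
        if anchor_mass_loss is None:
            t_final = float(obj.times_h[-1])
        else:
            t_final = obj.final_time_for(anchor_mass_loss)
        return MassLossCurve(
            obj.times_h,
            obj.mass_loss_pct,
            dimensionless_time=obj.times_h / t_final,
            label=obj.label,
        )
    raise TypeError(f"cannot align object of type {type(obj).__name__}")


def synth_experiment(
    true_params: PitParams,
    mesh_spec: dict | VoxelMesh,
    noise_sd: float = 1.0,
    n_times: int = 6,
    seed: int = 0,
    final_mass_loss: float = 89.27,
) -> ImmersionDataset:
    """Pseudo-experiment for parameter-recovery studies.

    Simulates a coupon with known ``true_params`` until ``final_mass_loss``
    percent, samples the curve at ``n_times`` evenly spaced dimensionless
    times (including tau = 0 and 1), adds i.i.d. Gaussian noise of standard
    deviation ``noise_sd`` (percentage points) truncated to [0, 100], and
    forces the (0, 0) point.  ``seed`` controls only the measurement noise;
    the simulation stream comes from ``true_params.seed``, so two noise
    seeds share the same underlying curve.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_times < 2:
        raise ValueError("need at least the (0,0) point and one sample")
    mesh = mesh_spec if isinstance(mesh_spec, VoxelMesh) else build_coupon_mesh(**mesh_spec)
    curve = simulate(mesh, true_params, mass_loss_target=final_mass_loss)
    curve = to_dimensionless(curve, anchor_mass_loss=final_mass_loss)
    tau = np.linspace(0.0, 1.0, n_times)
    clean = curve.interp(tau)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    noisy = np.clip(noisy, 0.0, 100.0)
    noisy = np.maximum.accumulate(noisy)  # keep the series a valid mass-loss curve
    noisy[0] = 0.0
    t_final_days = curve.final_time_for(final_mass_loss) / 24.0
    return ImmersionDataset(
        times_days=tau * t_final_days,
        mass_loss_pct=noisy,
        n_samples=1,
        label=f"synthetic (seed={seed}, noise_sd={noise_sd})",
    )
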
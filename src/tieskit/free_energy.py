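"""Ensemble thermodynamic-integration estimator with bootstrap uncertainty.

The free-energy change of one alchemical leg is ΔG = ∫₀¹ ⟨∂U/∂λ⟩_λ dλ.
Each λ window is sampled by an ensemble of independent replicas (same
system, different initial velocities); chaotic divergence of MD
trajectories makes the inter-replica spread of window means the dominant
source of uncertainty, so the bootstrap resamples *replica means*, not
individual timesteps. The integral is evaluated by trapezoidal quadrature
and window standard errors are propagated assuming independent windows:

    ΔG = Σ_i w_i m_i,     σ² = Σ_i w_i² se_i²

with w_i the trapezoidal weight of window i. The relative binding free
energy of a ligand pair combines the two legs of the thermodynamic cycle,
ΔΔG = ΔG_complex − ΔG_ligand, with σ² = σ²_complex + σ²_ligand.

All units are kcal/mol. Every random choice derives from a master seed
through stable per-(transformation, leg, window) hashing, so results are
independent of evaluation order and byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import math
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError

COMPLEX = "complex"
LIGAND = "ligand"

DEFAULT_N_BOOT = 5000
#: Progressive-protocol defaults: precision target and starting ensemble size.
SIGMA_THRESHOLD = 0.5   # kcal/mol
FLOOR_ENSEMBLE_SIZE = 5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GradientSamples:
    """∂U/∂λ time series of one replica at one λ window (kcal/mol)."""

    transformation_id: str
    leg: str
    lam: float
    replica: int
    samples: np.ndarray
    interval_ps: float = 2.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise DegenerateDataError(
                f"empty gradient series ({self.transformation_id}/{self.leg}"
                f"/λ={self.lam}/rep {self.replica})")
        if not np.all(np.isfinite(self.samples)):
            raise DegenerateDataError(
                f"non-finite gradients ({self.transformation_id}/{self.leg}"
                f"/λ={self.lam}/rep {self.replica})")


@dataclass
class WindowEnsemble:
    """Per-replica gradient series at every λ window of one leg."""

    transformation_id: str
    leg: str
    windows: dict[float, list[GradientSamples]]

    def __post_init__(self):
        for lam, reps in self.windows.items():
            if not reps:
                raise DegenerateDataError(f"window λ={lam} has no replicas")
            idx = [r.replica for r in reps]
            if len(set(idx)) != len(idx):
                raise ConfigurationError(f"duplicate replica indices at λ={lam}")
            reps.sort(key=lambda r: r.replica)

    @property
    def lambdas(self) -> list[float]:
        return sorted(self.windows)

    @property
    def ensemble_size(self) -> int:
        return min(len(reps) for reps in self.windows.values())

    def subset(self, replica_indices: dict[float, list[int]]) -> "WindowEnsemble":
        """Restrict each window to the given replica indices."""
        windows = {}
        for lam, reps in self.windows.items():
            keep = set(replica_indices[lam])
            windows[lam] = [r for r in reps if r.replica in keep]
        return WindowEnsemble(self.transformation_id, self.leg, windows)


@dataclass
class FreeEnergyResult:
    """ΔG of one leg with standard error and per-window statistics."""

    leg: str
    delta_g: float
    sigma: float
    per_window: list[tuple[float, float, float]]  # (λ, mean, se)
    ensemble_size: int
    n_boot: int
    seed: int | None
    transformation_id: str = ""


@dataclass
class DDGResult:
    """Relative binding free energy of one transformation (kcal/mol).

    ``sigma`` is None for single-replica estimates, where no uncertainty
    can be quantified.
    """

    transformation_id: str
    ddg: float
    sigma: float | None
    complex_leg: FreeEnergyResult | None = None
    ligand_leg: FreeEnergyResult | None = None
    ensemble_size: int | None = None


# ---------------------------------------------------------------------------
# Estimator components
# ---------------------------------------------------------------------------

def replica_means(window: list[GradientSamples],
                  discard_fraction: float = 0.0) -> np.ndarray:
    """Mean ∂U/∂λ of each replica after discarding the leading fraction.

    Production data are assumed equilibrated, so the default discards
    nothing; the fraction exists for raw streams.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ConfigurationError("discard_fraction must be in [0, 1)")
    out = []
    for rep in window:
        start = int(len(rep.samples) * discard_fraction)
        kept = rep.samples[start:]
        if kept.size == 0:
            raise DegenerateDataError(
                f"no samples left after discarding {discard_fraction:.0%} "
                f"(λ={rep.lam}, rep {rep.replica})")
        out.append(float(np.mean(kept)))
    return np.asarray(out)


def bootstrap_window(means: np.ndarray, n_boot: int = DEFAULT_N_BOOT,
                     resample_size: int | None = None,
                     seed: int | None = None,
                     return_resamples: bool = False):
    """Bootstrap the ensemble mean of one window from per-replica means.

    Draws ``n_boot`` resamples of ``resample_size`` replicas with
    replacement; returns the grand mean of the resample means and their
    population standard deviation as the standard error. With a single
    replica the spread is unquantifiable: se = 0 with a warning.
    """
    means = np.asarray(means, dtype=float)
    n = means.size
    if n == 0:
        raise DegenerateDataError("bootstrap_window needs at least one replica")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    if resample_size is None:
        resample_size = n
    if n == 1:
        _warnings.warn("single replica: bootstrap se set to 0", stacklevel=2)
        res = np.full(n_boot, means[0])
        return (means[0], 0.0, res) if return_resamples else (float(means[0]), 0.0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, resample_size))
    resample_means = means[idx].mean(axis=1)
    mean = float(resample_means.mean())
    se = float(resample_means.std(ddof=0))
    if return_resamples:
        return mean, se, resample_means
    return mean, se


def trapezoid_weights(lams: np.ndarray) -> np.ndarray:
    """Quadrature weight of each window under the composite trapezoid rule."""
    lams = np.asarray(lams, dtype=float)
    w = np.zeros_like(lams)
    d = np.diff(lams)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def integrate_profile(per_window: list[tuple[float, float, float]],
                      leg: str = "", transformation_id: str = "",
                      ensemble_size: int = 0, n_boot: int = 0,
                      seed: int | None = None) -> FreeEnergyResult:
    """Trapezoidal quadrature of a (λ, mean, se) profile over [0, 1].

    ΔG integrates the window means; σ propagates the window standard
    errors through the quadrature weights, treating windows as
    independent. Windows must be sorted, unique, and span λ = 0 to 1.
    """
    lams = np.array([p[0] for p in per_window], dtype=float)
    if lams.size < 2:
        raise ConfigurationError("need at least the two endpoint windows")
    if np.any(np.diff(lams) <= 0):
        raise ConfigurationError("windows must be sorted by λ with no duplicates")
    if abs(lams[0]) > 1e-9 or abs(lams[-1] - 1.0) > 1e-9:
        raise ConfigurationError("profile must span λ = 0 to λ = 1")
    means = np.array([p[1] for p in per_window], dtype=float)
    ses = np.array([p[2] for p in per_window], dtype=float)
    w = trapezoid_weights(lams)
    delta_g = float(w @ means)
    sigma = float(math.sqrt(np.sum(w ** 2 * ses ** 2)))
    return FreeEnergyResult(leg=leg, delta_g=delta_g, sigma=sigma,
                            per_window=[tuple(p) for p in per_window],
                            ensemble_size=ensemble_size, n_boot=n_boot,
                            seed=seed, transformation_id=transformation_id)


def window_seed(master_seed: int, transformation_id: str, leg: str, lam: float) -> int:
    """Stable sub-seed for one (transformation, leg, window) RNG stream."""
    key = f"{master_seed}:{transformation_id}:{leg}:{lam:.9f}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def estimate_leg(ens: WindowEnsemble, n_boot: int = DEFAULT_N_BOOT,
                 seed: int = 0, discard_fraction: float = 0.0,
                 resample_size: int | None = None) -> FreeEnergyResult:
    """Full TI estimate of one leg: replica means → per-window bootstrap →
    trapezoidal integration with error propagation."""
    per_window = []
    for lam in ens.lambdas:
        means = replica_means(ens.windows[lam], discard_fraction)
        m, se = bootstrap_window(
            means, n_boot=n_boot, resample_size=resample_size,
            seed=window_seed(seed, ens.transformation_id, ens.leg, lam))
        per_window.append((lam, m, se))
    return integrate_profile(per_window, leg=ens.leg,
                             transformation_id=ens.transformation_id,
                             ensemble_size=ens.ensemble_size,
                             n_boot=n_boot, seed=seed)


def ddg(complex_result: FreeEnergyResult, ligand_result: FreeEnergyResult) -> DDGResult:
    """Thermodynamic-cycle ΔΔG = ΔG_complex − ΔG_ligand with combined σ."""
    if complex_result.transformation_id != ligand_result.transformation_id:
        raise ConfigurationError(
            "legs belong to different transformations: "
            f"{complex_result.transformation_id!r} vs {ligand_result.transformation_id!r}")
    lams_c = [p[0] for p in complex_result.per_window]
    lams_l = [p[0] for p in ligand_result.per_window]
    if lams_c != lams_l:
        raise ConfigurationError("legs were computed on different λ schedules")
    return DDGResult(
        transformation_id=complex_result.transformation_id,
        ddg=complex_result.delta_g - ligand_result.delta_g,
        sigma=math.sqrt(complex_result.sigma ** 2 + ligand_result.sigma ** 2),
        complex_leg=complex_result,
        ligand_leg=ligand_result,
        ensemble_size=min(complex_result.ensemble_size, ligand_result.ensemble_size),
    )


def estimate_transformation(complex_ens: WindowEnsemble, ligand_ens: WindowEnsemble,
                            n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                            discard_fraction: float = 0.0) -> DDGResult:
    """Convenience composition: estimate both legs, combine the cycle."""
    return ddg(estimate_leg(complex_ens, n_boot, seed, discard_fraction),
               estimate_leg(ligand_ens, n_boot, seed, discard_fraction))


# ---------------------------------------------------------------------------
# Convergence and replica analyses
# ---------------------------------------------------------------------------

def subsample_convergence(complex_ens: WindowEnsemble, ligand_ens: WindowEnsemble,
                          sizes: list[int], n_subsets: int = 10, seed: int = 0,
                          n_boot: int = 1000) -> pd.DataFrame:
    """Precision versus ensemble size by replica subsampling.

    For each requested size k, draws ``n_subsets`` random k-replica subsets
    (without replacement, independently per window) and re-estimates ΔΔG;
    reports the average ΔΔG and average σ per size. On well-behaved data
    σ shrinks as the ensemble grows.
    """
    avail = min(complex_ens.ensemble_size, ligand_ens.ensemble_size)
    if max(sizes) > avail:
        raise ConfigurationError(
            f"requested size {max(sizes)} exceeds available replicas ({avail})")
    rng = np.random.default_rng(seed)
    rows = []
    for k in sorted(sizes):
        if k == avail and n_subsets == 1:
            # the only k-subset is the full ensemble: identical to a direct estimate
            res = estimate_transformation(complex_ens, ligand_ens,
                                          n_boot=n_boot, seed=seed)
            rows.append({"size": k, "mean_ddg": res.ddg,
                         "mean_sigma": res.sigma, "n_subsets": 1})
            continue
        ddgs, sigmas = [], []
        for s in range(n_subsets):
            sub_seed = int(rng.integers(0, 2 ** 31))
            pair = []
            for ens in (complex_ens, ligand_ens):
                choice = {
                    lam: sorted(rng.choice([r.replica for r in reps], size=k,
                                           replace=False).tolist())
                    for lam, reps in ens.windows.items()}
                pair.append(ens.subset(choice))
            res = estimate_transformation(pair[0], pair[1], n_boot=n_boot, seed=sub_seed)
            ddgs.append(res.ddg)
            sigmas.append(res.sigma)
        rows.append({"size": k, "mean_ddg": float(np.mean(ddgs)),
                     "mean_sigma": float(np.mean(sigmas)), "n_subsets": n_subsets})
    return pd.DataFrame(rows)


def replica_slice_estimate(complex_ens: WindowEnsemble, ligand_ens: WindowEnsemble,
                           replica_index: int) -> DDGResult:
    """One-off-simulation surrogate: TI using a single replica per window.

    Takes the series of the given replica index at every window of both
    legs; no bootstrap is performed and σ is reported as absent (None).
    """
    legs = []
    for ens in (complex_ens, ligand_ens):
        per_window = []
        for lam in ens.lambdas:
            match = [r for r in ens.windows[lam] if r.replica == replica_index]
            if not match:
                raise ConfigurationError(
                    f"replica {replica_index} missing at λ={lam} ({ens.leg} leg)")
            per_window.append((lam, float(np.mean(match[0].samples)), 0.0))
        legs.append(integrate_profile(per_window, leg=ens.leg,
                                      transformation_id=ens.transformation_id,
                                      ensemble_size=1, n_boot=0, seed=None))
    return DDGResult(
        transformation_id=complex_ens.transformation_id,
        ddg=legs[0].delta_g - legs[1].delta_g,
        sigma=None,
        complex_leg=legs[0], ligand_leg=legs[1], ensemble_size=1,
    )


@dataclass
class EscalationPlan:
    """Progressive-protocol outcome for one transformation."""

    transformation_id: str
    sigma: float
    current_size: int
    status: str               # "converged" | "escalate" | "unconverged_at_budget"
    next_size: int | None = None


def progressive_protocol(results: list[DDGResult],
                         sigma_threshold: float = SIGMA_THRESHOLD,
                         floor_size: int = FLOOR_ENSEMBLE_SIZE,
                         step: int = 5, max_size: int = 40) -> list[EscalationPlan]:
    """Adaptive ensemble sizing: escalate only imprecise transformations.

    Start every transformation at the floor ensemble size; any whose σ
    exceeds the threshold is assigned the next size (current + step, capped
    at ``max_size``); transformations already at the cap that remain above
    threshold are flagged unconverged at budget.
    """
    plan = []
    for r in results:
        size = r.ensemble_size if r.ensemble_size is not None else floor_size
        if r.sigma is None:
            raise ConfigurationError(
                f"{r.transformation_id}: progressive protocol needs a σ estimate")
        if r.sigma <= sigma_threshold:
            plan.append(EscalationPlan(r.transformation_id, r.sigma, size, "converged"))
        elif size >= max_size:
            plan.append(EscalationPlan(r.transformation_id, r.sigma, size,
                                       "unconverged_at_budget"))
        else:
            plan.append(EscalationPlan(r.transformation_id, r.sigma, size,
                                       "escalate", next_size=min(size + step, max_size)))
    return plan
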
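"""Synthetic gradient ensembles, benchmark tables and toy ligand pairs.

Ensemble TI data cannot be regenerated without weeks of MD, so this module
emulates their statistical structure around a known ground truth:

* the mean ∂U/∂λ profile of each leg is a polynomial in λ whose exact
  integral (the true ΔG) is known in closed form;
* each replica carries a persistent offset drawn from a configurable,
  generally non-normal family — replicas of real ensembles diverge from
  their initial conditions and their window means spread by many kcal/mol,
  far more than the within-replica sampling noise;
* within-replica fluctuations are iid Gaussian by default (samples taken
  every 2 ps are treated as effectively independent), with an optional
  AR(1) mode.

Offset families are standardized to zero mean and unit variance before
scaling, so the expected window mean always equals the true profile.
All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .benchmark_metrics import BenchmarkRecord
from .errors import ConfigurationError
from .free_energy import COMPLEX, LIGAND, GradientSamples, WindowEnsemble, window_seed
from .lambda_protocol import STANDARD_LAMBDAS
from .ligand_topology import AtomRecord, LigandGraph

OFFSET_FAMILIES = ("normal", "skew_normal", "student_t", "mixture")


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class TruthSpec:
    """Ground-truth mean-gradient profiles of the two legs.

    Coefficients are ascending-power polynomial coefficients of the mean
    ∂U/∂λ profile (kcal/mol); the true leg ΔG is the analytic integral of
    that polynomial over [0, 1].
    """

    complex_coeffs: tuple[float, ...] = (10.0, -30.0, 15.0)
    ligand_coeffs: tuple[float, ...] = (8.0, -25.0, 12.0)

    @staticmethod
    def _integral(coeffs) -> float:
        return float(sum(c / (k + 1) for k, c in enumerate(coeffs)))

    @property
    def true_dg_complex(self) -> float:
        return self._integral(self.complex_coeffs)

    @property
    def true_dg_ligand(self) -> float:
        return self._integral(self.ligand_coeffs)

    @property
    def true_ddg(self) -> float:
        return self.true_dg_complex - self.true_dg_ligand

    def profile(self, leg: str, lam) -> np.ndarray:
        coeffs = self.complex_coeffs if leg == COMPLEX else self.ligand_coeffs
        return np.polynomial.polynomial.polyval(np.asarray(lam, dtype=float),
                                                np.asarray(coeffs, dtype=float))


@dataclass
class NoiseSpec:
    """Stochastic structure of a simulated ensemble.

    ``replica_offset_scale`` is the standard deviation (kcal/mol) of the
    per-replica offset; the default 5 kcal/mol reproduces the observed
    regime where window means range over ~20 kcal/mol across tens of
    replicas. ``within_replica_scale`` is the sd of per-timestep noise.
    Offsets are persistent across λ windows by default (initial-condition
    divergence affects the whole profile of a replica);
    ``per_window_offsets`` draws them independently per window instead,
    matching the estimator's independent-window error model.
    """

    replica_offset_family: str = "normal"
    replica_offset_scale: float = 5.0
    within_replica_scale: float = 2.0
    skew_alpha: float = 5.0
    student_df: float = 5.0
    mixture_weight: float = 0.2
    mixture_separation: float = 2.0
    per_window_offsets: bool = False
    ar1_rho: float = 0.0

    def __post_init__(self):
        if self.replica_offset_family not in OFFSET_FAMILIES:
            raise ConfigurationError(
                f"unknown offset family {self.replica_offset_family!r}")
        if self.replica_offset_scale < 0 or self.within_replica_scale < 0:
            raise ConfigurationError("noise scales must be >= 0")
        if self.replica_offset_family == "student_t" and self.student_df <= 2:
            raise ConfigurationError("student_t family needs df > 2 for finite variance")
        if not 0.0 < self.mixture_weight < 1.0:
            raise ConfigurationError("mixture_weight must be in (0, 1)")
        if (self.replica_offset_family == "mixture"
                and self.mixture_weight * (1 - self.mixture_weight)
                * self.mixture_separation ** 2 >= 1.0):
            raise ConfigurationError(
                "mixture_separation too large for unit total variance")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ConfigurationError("ar1_rho must be in [0, 1)")


def draw_offsets(noise: NoiseSpec, size, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, sd = ``replica_offset_scale`` draws from the offset family."""
    scale = noise.replica_offset_scale
    fam = noise.replica_offset_family
    if scale == 0.0:
        return np.zeros(size)
    if fam == "normal":
        z = rng.standard_normal(size)
    elif fam == "skew_normal":
        a = noise.skew_alpha
        delta = a / np.sqrt(1.0 + a * a)
        raw = stats.skewnorm.rvs(a, size=size, random_state=rng)
        mu = delta * np.sqrt(2.0 / np.pi)
        sd = np.sqrt(1.0 - 2.0 * delta * delta / np.pi)
        z = (raw - mu) / sd
    elif fam == "student_t":
        df = noise.student_df
        z = stats.t.rvs(df, size=size, random_state=rng) / np.sqrt(df / (df - 2.0))
    else:  # mixture of two normals, zero mean, unit variance
        w, d = noise.mixture_weight, noise.mixture_separation
        means = np.where(rng.random(size) < w, (1.0 - w) * d, -w * d)
        var_between = w * (1 - w) * d * d
        z = means + rng.standard_normal(size) * np.sqrt(1.0 - var_between)
    return scale * z


# ---------------------------------------------------------------------------
# Gradient ensembles
# ---------------------------------------------------------------------------

def simulate_leg(truth: TruthSpec, noise: NoiseSpec, leg: str = COMPLEX,
                 schedule=STANDARD_LAMBDAS, n_replicas: int = 5,
                 n_samples: int = 2000, seed: int = 0,
                 transformation_id: str = "synthetic") -> WindowEnsemble:
    """Simulate the per-replica ∂U/∂λ series of one leg.

    Each replica's samples at window λ are
    ``profile(λ) + offset_replica + ε_t`` with ε_t the within-replica
    noise. The expected window mean equals the true profile, so the
    trapezoid of the truth is the recoverable ΔG. Fixed seed gives
    identical output.
    """
    if n_replicas < 1 or n_samples < 1:
        raise ConfigurationError("n_replicas and n_samples must be >= 1")
    rng = np.random.default_rng(window_seed(seed, transformation_id, leg, -1.0))
    persistent = draw_offsets(noise, n_replicas, rng)
    windows: dict[float, list[GradientSamples]] = {}
    for lam in schedule:
        wrng = np.random.default_rng(window_seed(seed, transformation_id, leg, lam))
        offsets = (draw_offsets(noise, n_replicas, wrng)
                   if noise.per_window_offsets else persistent)
        base = float(truth.profile(leg, lam))
        reps = []
        for k in range(n_replicas):
            eps = wrng.standard_normal(n_samples) * noise.within_replica_scale
            if noise.ar1_rho > 0.0:
                eps = _ar1_filter(eps, noise.ar1_rho)
            reps.append(GradientSamples(
                transformation_id=transformation_id, leg=leg, lam=float(lam),
                replica=k + 1, samples=base + offsets[k] + eps))
        windows[float(lam)] = reps
    return WindowEnsemble(transformation_id, leg, windows)


def _ar1_filter(eps: np.ndarray, rho: float) -> np.ndarray:
    """Color white noise as AR(1) with the same stationary variance."""
    out = np.empty_like(eps)
    out[0] = eps[0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, eps.size):
        out[t] = rho * out[t - 1] + c * eps[t]
    return out


def simulate_transformation(truth: TruthSpec, noise: NoiseSpec,
                            schedule=STANDARD_LAMBDAS, n_replicas: int = 5,
                            n_samples: int = 2000, seed: int = 0,
                            transformation_id: str = "synthetic"):
    """Both legs of one transformation with independent noise streams.

    Returns ``(complex_ensemble, ligand_ensemble, true_ddg)``; the true
    ΔΔG is recorded for recovery tests.
    """
    cplx = simulate_leg(truth, noise, COMPLEX, schedule, n_replicas,
                        n_samples, seed, transformation_id)
    lig = simulate_leg(truth, noise, LIGAND, schedule, n_replicas,
                       n_samples, seed, transformation_id)
    return cplx, lig, truth.true_ddg


# ---------------------------------------------------------------------------
# Benchmark tables
# ---------------------------------------------------------------------------

def simulate_benchmark(n_pairs: int, exp_range: float = 3.0,
                       error_sd: float = 1.0, error_family: str = "normal",
                       skew_alpha: float = 5.0, seed: int = 0,
                       system: str = "synthetic") -> list[BenchmarkRecord]:
    """Paired experimental/predicted ΔΔG values with known error structure.

    Experimental values are uniform on [−``exp_range``, ``exp_range``];
    predictions add zero-mean errors of sd ``error_sd`` from the chosen
    family, so the generating RMSE is ``error_sd`` and (for normal errors)
    the generating MUE is ``error_sd·√(2/π)``.
    """
    if n_pairs < 2:
        raise ConfigurationError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    exp = rng.uniform(-exp_range, exp_range, size=n_pairs)
    noise = NoiseSpec(replica_offset_family=error_family,
                      replica_offset_scale=error_sd, skew_alpha=skew_alpha)
    err = draw_offsets(noise, n_pairs, rng)
    sigmas = np.abs(rng.normal(0.3, 0.1, size=n_pairs)) + 0.05
    return [BenchmarkRecord(pair_id=f"pair{i + 1:03d}", system=system,
                            ddg_pred=float(exp[i] + err[i]),
                            ddg_exp=float(exp[i]),
                            sigma_pred=float(sigmas[i]))
            for i in range(n_pairs)]


# ---------------------------------------------------------------------------
# Toy ligand pairs
# ---------------------------------------------------------------------------

TOY_TEMPLATES = ("benzene_toluene", "ring_swap", "charged_tail", "custom")

#: Common atom receiving the charge perturbation in each template (B-side id).
_PERTURBED_ATOM = {"benzene_toluene": 3, "ring_swap": 3, "charged_tail": 2}


def _ring(n_carbons: int, charge: float, start_id: int = 0):
    atoms = [AtomRecord(start_id + i, "C", f"C{i + 1}", charge)
             for i in range(n_carbons)]
    bonds = [(start_id + i, start_id + (i + 1) % n_carbons, 1)
             for i in range(n_carbons)]
    return atoms, bonds


def toy_ligand_pair(template: str = "benzene_toluene",
                    charge_perturbation: float = 0.0, seed: int = 0,
                    custom_pair=None) -> tuple[LigandGraph, LigandGraph]:
    """Small heavy-atom ligand pairs with assigned partial charges.

    Templates:

    * ``benzene_toluene`` — 6-ring versus 6-ring + methyl; common ring of 6.
    * ``ring_swap`` — benzene versus pyridine; the element change limits
      the common substructure to a 5-carbon path.
    * ``charged_tail`` — a neutral chain versus the same chain with a net
      +1 amine tail in the non-common region (charged alchemical region).
    * ``custom`` — returns ``custom_pair`` unchanged.

    ``charge_perturbation`` is added to the partial charge of one canonical
    common atom of ligand B, so a 0.15 e perturbation makes exactly one
    mapped pair violate the default 0.1 e tolerance. ``seed`` draws a
    common-mode charge jitter applied identically to matched atoms of A
    and B (it varies the pair without touching charge differences).
    """
    if template not in TOY_TEMPLATES:
        raise ConfigurationError(f"unknown toy template {template!r}")
    if template == "custom":
        if custom_pair is None:
            raise ConfigurationError("custom template requires custom_pair=(a, b)")
        return custom_pair

    rng = np.random.default_rng(seed)

    if template == "benzene_toluene":
        a_atoms, a_bonds = _ring(6, -0.10)
        a = LigandGraph(a_atoms, a_bonds, net_charge=0, name="benzene")
        b_atoms, b_bonds = _ring(6, -0.10)
        b_atoms[0] = AtomRecord(0, "C", "C1", -0.05)     # ipso carbon
        b_atoms.append(AtomRecord(6, "C", "C7", -0.30))  # methyl carbon
        b_bonds.append((0, 6, 1))
        b = LigandGraph(b_atoms, b_bonds, net_charge=0, name="toluene")
        common = {i: i for i in range(6)}
    elif template == "ring_swap":
        a_atoms, a_bonds = _ring(6, -0.08)
        a = LigandGraph(a_atoms, a_bonds, net_charge=0, name="benzene")
        b_atoms, b_bonds = _ring(6, -0.08)
        b_atoms[0] = AtomRecord(0, "N", "N1", -0.55)
        b_atoms[1] = AtomRecord(1, "C", "C2", 0.20)
        b_atoms[5] = AtomRecord(5, "C", "C6", 0.20)
        b = LigandGraph(b_atoms, b_bonds, net_charge=0, name="pyridine")
        common = {i: i for i in range(1, 6)}
    else:  # charged_tail
        a_atoms = [AtomRecord(i, "C", f"C{i + 1}", -0.05) for i in range(4)]
        a_bonds = [(i, i + 1, 1) for i in range(3)]
        a = LigandGraph(a_atoms, a_bonds, net_charge=0, name="butane")
        b_atoms = [AtomRecord(i, "C", f"C{i + 1}", -0.05) for i in range(4)]
        b_bonds = [(i, i + 1, 1) for i in range(3)]
        b_atoms += [AtomRecord(4, "C", "C5", 0.25), AtomRecord(5, "N", "N1", 0.75)]
        b_bonds += [(3, 4, 1), (4, 5, 1)]
        b = LigandGraph(b_atoms, b_bonds, net_charge=1, name="butylamine-cation")
        common = {i: i for i in range(4)}

    # common-mode jitter: same perturbation on matched atoms, Δq unchanged
    jitter = rng.uniform(-0.005, 0.005, size=len(common))
    a = _adjust_charges(a, {ai: j for (ai, _), j in zip(common.items(), jitter)})
    b = _adjust_charges(b, {bi: j for (_, bi), j in zip(common.items(), jitter)})
    if charge_perturbation:
        b = _adjust_charges(b, {_PERTURBED_ATOM[template]: charge_perturbation})
    return a, b


def _adjust_charges(g: LigandGraph, deltas: dict[int, float]) -> LigandGraph:
    atoms = [AtomRecord(a.atom_id, a.element, a.name,
                        a.partial_charge + deltas.get(a.atom_id, 0.0), a.coords)
             for a in g.atoms]
    return LigandGraph(atoms, list(g.bonds), net_charge=g.net_charge, name=g.name)


def random_ligand_pair(seed: int, n_heavy_a: int = 10, n_heavy_b: int = 10,
                       elements=("C", "C", "C", "N", "O"),
                       charge_scale: float = 0.15) -> tuple[LigandGraph, LigandGraph]:
    """Random connected heavy-atom ligand pair sharing a perturbed core.

    Builds a random tree plus occasional ring-closing edges for ligand A,
    then derives ligand B by relabeling a few elements, regrowing a few
    atoms and re-drawing charges — producing pairs with a nontrivial
    common substructure for exhaustive-search cross-checks.
    """
    rng = np.random.default_rng(seed)

    def random_graph(n, name):
        atoms = [AtomRecord(i, str(rng.choice(elements)), f"X{i}",
                            float(rng.normal(0.0, charge_scale)))
                 for i in range(n)]
        bonds = [(int(rng.integers(0, i)), i, 1) for i in range(1, n)]
        for _ in range(int(rng.integers(0, 2))):
            i, j = rng.integers(0, n, size=2)
            if i != j and (min(i, j), max(i, j), 1) not in bonds:
                bonds.append((min(int(i), int(j)), max(int(i), int(j)), 1))
        return LigandGraph(atoms, bonds, name=name)

    a = random_graph(n_heavy_a, f"rand{seed}A")
    # ligand B: start from A's topology, mutate elements/charges, regrow tail
    b_atoms = []
    for atom in a.atoms[:n_heavy_b]:
        elem = atom.element
        if rng.random() < 0.2:
            elem = str(rng.choice(elements))
        b_atoms.append(AtomRecord(atom.atom_id, elem, atom.name,
                                  float(rng.normal(0.0, charge_scale))))
    b_bonds = [(i, j, o) for i, j, o in a.bonds
               if i < len(b_atoms) and j < len(b_atoms)]
    for i in range(len(b_atoms), n_heavy_b):
        b_atoms.append(AtomRecord(i, str(rng.choice(elements)), f"X{i}",
                                  float(rng.normal(0.0, charge_scale))))
        b_bonds.append((int(rng.integers(0, i)), i, 1))
    b = LigandGraph(b_atoms, b_bonds, name=f"rand{seed}B")
    return a, b
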
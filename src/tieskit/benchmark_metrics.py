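"""Accuracy statistics for predicted-versus-experimental ΔΔG tables.

Summary statistics for benchmark studies: mean unsigned error (MUE),
root-mean-square error (RMSE), and Pearson's correlation r_p between
predicted and experimental relative binding free energies, each with a
nonparametric pair-level bootstrap standard error. Also provided:
binning by the magnitude of the experimental value (narrow dynamic ranges
attenuate r even at fixed error), fractions of predictions within fixed
chemical-accuracy thresholds, and correlations of error/uncertainty with
alchemical-region size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError

DEFAULT_N_BOOT = 10_000
DEFAULT_BIN_EDGES = (1.0, 2.0, 3.0)
DEFAULT_THRESHOLDS = (0.5, 1.0, 1.5, 2.0)


@dataclass
class BenchmarkRecord:
    """One ligand pair: predicted and experimental ΔΔG (kcal/mol).

    ``n_dis``/``n_app`` annotations (alchemical atom counts) are optional
    and only required for size-correlation analyses.
    """

    pair_id: str
    ddg_pred: float
    ddg_exp: float
    sigma_pred: float | None = None
    system: str = ""
    n_dis: int | None = None
    n_app: int | None = None

    def __post_init__(self):
        if not (np.isfinite(self.ddg_pred) and np.isfinite(self.ddg_exp)):
            raise DegenerateDataError(f"non-finite ΔΔG for pair {self.pair_id!r}")
        if self.sigma_pred is not None and self.sigma_pred < 0:
            raise DegenerateDataError(f"negative σ for pair {self.pair_id!r}")


@dataclass
class MetricsReport:
    """MUE/RMSE/Pearson r with bootstrap standard errors (kcal/mol)."""

    n: int
    mue: float
    rmse: float
    pearson_r: float | None
    se_mue: float
    se_rmse: float
    se_r: float | None
    n_boot: int
    seed: int | None
    diagnostic: str | None = None

    def as_dict(self) -> dict:
        return {
            "n": self.n, "mue": self.mue, "rmse": self.rmse,
            "pearson_r": self.pearson_r, "se_mue": self.se_mue,
            "se_rmse": self.se_rmse, "se_r": self.se_r,
            "n_boot": self.n_boot, "seed": self.seed,
            "diagnostic": self.diagnostic,
        }


def _arrays(records) -> tuple[np.ndarray, np.ndarray]:
    pred = np.array([r.ddg_pred for r in records], dtype=float)
    exp = np.array([r.ddg_exp for r in records], dtype=float)
    return pred, exp


def metrics(records, n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> MetricsReport:
    """MUE, RMSE and Pearson r with pair-level bootstrap standard errors.

    Resamples whole (predicted, experimental) pairs with replacement;
    each SE is the standard deviation of the metric over the resamples.
    With zero experimental variance the correlation is undefined and
    reported as absent.
    """
    records = list(records)
    if len(records) < 2:
        raise DegenerateDataError("metrics need at least 2 records")
    pred, exp = _arrays(records)
    err = pred - exp
    mue = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    diagnostic = None
    if np.ptp(exp) == 0.0 or np.ptp(pred) == 0.0:
        r = None
        diagnostic = "zero variance: Pearson r undefined"
    else:
        r = float(stats.pearsonr(pred, exp).statistic)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(records), size=(n_boot, len(records)))
    e = err[idx]
    boot_mue = np.abs(e).mean(axis=1)
    boot_rmse = np.sqrt((e ** 2).mean(axis=1))
    se_r = None
    if r is not None:
        p, x = pred[idx], exp[idx]
        px = (p * x).mean(axis=1) - p.mean(axis=1) * x.mean(axis=1)
        sp, sx = p.std(axis=1), x.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boot_r = px / (sp * sx)
        finite = boot_r[np.isfinite(boot_r)]  # drop degenerate resamples
        se_r = float(finite.std(ddof=0)) if finite.size else None
    return MetricsReport(
        n=len(records), mue=mue, rmse=rmse, pearson_r=r,
        se_mue=float(boot_mue.std(ddof=0)), se_rmse=float(boot_rmse.std(ddof=0)),
        se_r=se_r, n_boot=n_boot, seed=seed, diagnostic=diagnostic,
    )


def bin_by_experimental(records, edges=DEFAULT_BIN_EDGES,
                        n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> pd.DataFrame:
    """Per-bin accuracy, binning on the magnitude of the experimental ΔΔG.

    Bins are [0, e₁), [e₁, e₂), ..., [e_k, ∞) on |ΔΔG_exp|. Bins with
    fewer than 2 records report the count only (metrics need n ≥ 2).
    """
    edges = sorted(float(e) for e in edges)
    if any(e <= 0 for e in edges):
        raise ConfigurationError("bin edges must be positive")
    records = list(records)
    bounds = [0.0, *edges, np.inf]
    rows = []
    for lo, hi in zip(bounds, bounds[1:]):
        sel = [r for r in records if lo <= abs(r.ddg_exp) < hi]
        label = f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">= {lo:g}"
        row = {"bin": label, "lo": lo, "hi": hi, "count": len(sel),
               "mue": None, "pearson_r": None, "se_mue": None, "se_r": None}
        if len(sel) >= 2:
            rep = metrics(sel, n_boot=n_boot, seed=seed)
            row.update(mue=rep.mue, pearson_r=rep.pearson_r,
                       se_mue=rep.se_mue, se_r=rep.se_r)
        rows.append(row)
    return pd.DataFrame(rows)


def threshold_fractions(records, thresholds=DEFAULT_THRESHOLDS) -> dict[float, float]:
    """Fraction of predictions within each |error| threshold (kcal/mol)."""
    thresholds = [float(t) for t in thresholds]
    if sorted(thresholds) != thresholds:
        raise ConfigurationError("thresholds must be sorted ascending")
    pred, exp = _arrays(list(records))
    err = np.abs(pred - exp)
    return {t: float(np.mean(err < t)) for t in thresholds}


def size_correlations(records, size_measure: str = "alchemical",
                      n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> dict:
    """Pearson correlation of |error| and of σ with alchemical-region size.

    ``size_measure`` is ``"alchemical"`` (n_dis + n_app) or
    ``"transformation"`` (|n_dis − n_app|). Records must carry n_dis/n_app
    annotations; σ correlations use only records with a σ estimate.
    Returns r values with pair-level bootstrap standard errors.
    """
    records = list(records)
    if size_measure not in ("alchemical", "transformation"):
        raise ConfigurationError(f"unknown size measure {size_measure!r}")
    if any(r.n_dis is None or r.n_app is None for r in records):
        raise DegenerateDataError("size correlations need n_dis/n_app annotations")

    def size_of(r):
        return (r.n_dis + r.n_app if size_measure == "alchemical"
                else abs(r.n_dis - r.n_app))

    sizes = np.array([size_of(r) for r in records], dtype=float)
    abs_err = np.array([abs(r.ddg_pred - r.ddg_exp) for r in records])
    out = {"size_measure": size_measure, "n": len(records), "n_boot": n_boot,
           "seed": seed}
    out["r_abs_error"], out["se_r_abs_error"] = _pearson_with_se(
        sizes, abs_err, n_boot, seed)
    with_sigma = [(size_of(r), r.sigma_pred) for r in records
                  if r.sigma_pred is not None]
    if len(with_sigma) >= 2:
        s, sg = map(np.asarray, zip(*with_sigma))
        out["r_sigma"], out["se_r_sigma"] = _pearson_with_se(
            s.astype(float), sg.astype(float), n_boot, seed + 1)
    else:
        out["r_sigma"] = out["se_r_sigma"] = None
    return out


def _pearson_with_se(x: np.ndarray, y: np.ndarray, n_boot: int, seed: int):
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None, None
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    xb, yb = x[idx], y[idx]
    cov = (xb * yb).mean(axis=1) - xb.mean(axis=1) * yb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = cov / (xb.std(axis=1) * yb.std(axis=1))
    finite = boot[np.isfinite(boot)]
    se = float(finite.std(ddof=0)) if finite.size else None
    return r, se


def records_from_dataframe(df: pd.DataFrame) -> list[BenchmarkRecord]:
    """Build records from a table with columns pair_id, ddg_pred, ddg_exp
    and optional sigma_pred, system, n_dis, n_app."""
    def opt(row, col, cast=float):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return cast(v)

    out = []
    for _, row in df.iterrows():
        out.append(BenchmarkRecord(
            pair_id=str(row["pair_id"]),
            ddg_pred=float(row["ddg_pred"]),
            ddg_exp=float(row["ddg_exp"]),
            sigma_pred=opt(row, "sigma_pred"),
            system=str(row.get("system", "") or ""),
            n_dis=opt(row, "n_dis", int),
            n_app=opt(row, "n_app", int),
        ))
    return out
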
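"""Smooth response surfaces of the sweep metrics over (offtake, phi).

Generalised additive models are fitted with ``mgcv`` (driven through
``Rscript``): a Gaussian-family smooth for the growth metrics and a
binomial-family smooth for extinction probability.  Because offtake
(0-10,000 birds) and return rate (0.60-0.84) live on very different
scales, the default smoother is a scale-invariant tensor-product smooth
``te(offtake, phi)``; an isotropic thin-plate smooth on standardised
covariates is available as an alternative.  Smoothness is selected by GCV.

Fits consume one observation per grid cell (the Monte-Carlo cell mean for
Gaussian metrics; extinct/total counts for the binomial metric) and
predict on the training grid only — contour queries never extrapolate.

Threshold extraction (zero-growth frontier, extinction-probability
contours) interpolates linearly between adjacent prediction-grid points;
raw-grid thresholds computed directly from cell means are reported
alongside the smoothed ones because the two can diverge for a surface
this steep.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import DemographicParams
from .scenarios import ScenarioGrid, run_grid, summarize_scenarios

__all__ = [
    "SurfaceFit",
    "fit_metric_surface",
    "zero_growth_frontier",
    "probability_contour",
    "empirical_zero_growth_frontier",
    "empirical_extinction_threshold",
    "k_sensitivity",
]

_R_TEMPLATE = """
suppressMessages(library(mgcv))
d <- read.csv("{data}")
{fit}
p <- read.csv("{pred}")
p$predicted <- as.numeric(predict(m, newdata = p, type = "response"))
write.csv(p, "{out}", row.names = FALSE)
writeLines(format(sum(m$edf), digits = 10), "{edf}")
"""


def _mgcv_formula(family: str, smoother: str, k_off: int, k_phi: int) -> str:
    lhs = "y" if family == "gaussian" else "cbind(successes, failures)"
    if smoother == "tensor":
        smooth = f"te(offtake, phi, k = c({k_off}, {k_phi}))"
    else:  # isotropic thin plate on standardised covariates
        smooth = f"s(offtake_std, phi_std, k = {k_off * k_phi})"
    fam = "" if family == "gaussian" else ", family = binomial"
    return f"m <- gam({lhs} ~ {smooth}, data = d{fam})"


@dataclass(frozen=True)
class SurfaceFit:
    """A fitted metric surface with its prediction grid and provenance."""

    metric: str
    family: str
    smoother: dict
    grid: pd.DataFrame  # columns: offtake, phi, predicted

    def __post_init__(self) -> None:
        if self.family == "binomial":
            pred = self.grid["predicted"]
            if ((pred < 0) | (pred > 1)).any():
                raise ValueError("binomial predictions must lie in [0, 1]")

    @property
    def offtake_values(self) -> np.ndarray:
        return np.sort(self.grid["offtake"].unique())

    @property
    def phi_values(self) -> np.ndarray:
        return np.sort(self.grid["phi"].unique())

    def predict(self, offtake, phi):
        """Bilinear interpolation on the prediction grid (no extrapolation)."""
        from scipy.interpolate import RegularGridInterpolator

        off = self.offtake_values
        ph = self.phi_values
        z = (self.grid.pivot(index="offtake", columns="phi", values="predicted")
             .loc[off, ph].to_numpy())
        interp = RegularGridInterpolator((off, ph), z, bounds_error=True)
        pts = np.column_stack([np.atleast_1d(offtake), np.atleast_1d(phi)])
        out = interp(pts)
        return float(out[0]) if np.isscalar(offtake) and np.isscalar(phi) else out

    def profile(self, phi: float) -> pd.DataFrame:
        s = self.grid[np.isclose(self.grid["phi"], phi)]
        if s.empty:
            raise ValueError(f"phi={phi} is not on the prediction grid")
        return s.sort_values("offtake").reset_index(drop=True)


def _require_rscript() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise RuntimeError("Rscript (with mgcv) is required for surface fitting")
    return exe


def fit_metric_surface(
    records: pd.DataFrame,
    metric: str = "growth_total",
    family: str = "gaussian",
    *,
    smoother: str = "tensor",
    basis_dim: tuple[int, int] | None = None,
) -> SurfaceFit:
    """Fit a smooth bivariate surface of a sweep metric on (offtake, phi).

    ``records`` is the per-replicate metrics table from the scenario engine
    (a pre-aggregated cell table with the ``summarize_scenarios`` columns is
    also accepted).  ``metric`` is a Gaussian-family response column
    (``growth_total`` or ``mean_annual_growth``) or ``extinct`` with
    ``family="binomial"``.  ``basis_dim`` gives the marginal basis dimensions
    (offtake, phi); the default (15, 8) is capped at the number of distinct
    grid levels per axis.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"family must be 'gaussian' or 'binomial', got {family!r}")
    if smoother not in ("tensor", "isotropic"):
        raise ValueError(f"smoother must be 'tensor' or 'isotropic', got {smoother!r}")
    if family == "binomial" and metric != "extinct":
        raise ValueError("binomial family applies to the 'extinct' metric")

    cells = _aggregate_cells(records, metric, family)
    n_off = cells["offtake"].nunique()
    n_phi = cells["phi"].nunique()
    if n_off < 2 or n_phi < 2:
        raise ValueError("surface fitting needs >= 2 distinct values on each axis")
    k_off, k_phi = basis_dim if basis_dim is not None else (15, 8)
    k_off = int(min(k_off, n_off))
    k_phi = int(min(k_phi, n_phi))
    if min(k_off, k_phi) < 2:
        raise ValueError("basis dimension must be >= 2 on each axis")

    pred = cells[["offtake", "phi"]].copy()
    data = cells.copy()
    if smoother == "isotropic":
        for frame in (data, pred):
            frame["offtake_std"] = _standardize(frame["offtake"], cells["offtake"])
            frame["phi_std"] = _standardize(frame["phi"], cells["phi"])

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        data.to_csv(tmp / "data.csv", index=False)
        pred.to_csv(tmp / "pred.csv", index=False)
        script = _R_TEMPLATE.format(
            data=tmp / "data.csv", pred=tmp / "pred.csv",
            out=tmp / "out.csv", edf=tmp / "edf.txt",
            fit=_mgcv_formula(family, smoother, k_off, k_phi),
        )
        (tmp / "fit.R").write_text(script)
        proc = subprocess.run(
            [_require_rscript(), "--vanilla", str(tmp / "fit.R")],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"mgcv fit failed:\n{proc.stderr}")
        out = pd.read_csv(tmp / "out.csv")
        edf = float((tmp / "edf.txt").read_text().strip())

    if family == "binomial":
        out["predicted"] = out["predicted"].clip(0.0, 1.0)
    provenance = {
        "engine": "mgcv",
        "smoother": smoother,
        "basis_dim": [k_off, k_phi],
        "method": "GCV",
        "edf": edf,
        "family": family,
    }
    return SurfaceFit(metric=metric, family=family, smoother=provenance,
                      grid=out[["offtake", "phi", "predicted"]])


def _standardize(x, ref) -> np.ndarray:
    ref = np.asarray(ref, dtype=float)
    sd = ref.std()
    return (np.asarray(x, dtype=float) - ref.mean()) / (sd if sd > 0 else 1.0)


def _aggregate_cells(records: pd.DataFrame, metric: str, family: str) -> pd.DataFrame:
    if family == "binomial":
        if "extinction_probability" in records.columns:  # summary table
            cells = records[["offtake", "phi", "n"]].copy()
            succ = np.rint(records["extinction_probability"] * records["n"]).astype(int)
        else:
            g = records.groupby(["offtake", "phi"], sort=True)["extinct"]
            cells = g.size().rename("n").reset_index()
            succ = g.sum().to_numpy().astype(int)
        cells["successes"] = succ
        cells["failures"] = cells["n"] - cells["successes"]
        return cells.drop(columns="n")
    summary_col = {"growth_total": "mean_growth_total",
                   "mean_annual_growth": "mean_annual_growth"}.get(metric, metric)
    if metric in records.columns and "replicate" in records.columns:
        cells = (records.groupby(["offtake", "phi"], sort=True)[metric]
                 .mean().rename("y").reset_index())
    elif summary_col in records.columns:
        cells = records[["offtake", "phi"]].copy()
        cells["y"] = records[summary_col].to_numpy()
    else:
        raise ValueError(f"metric {metric!r} not found in records")
    return cells


def _first_downward_crossing(offtake: np.ndarray, values: np.ndarray,
                             level: float) -> float:
    """Smallest offtake where values cross the level from above, linearly
    interpolated; NaN when no crossing (including already below at offtake 0)."""
    if values[0] <= level:
        return np.nan
    for a in range(len(values) - 1):
        if values[a] > level >= values[a + 1]:
            frac = (values[a] - level) / (values[a] - values[a + 1])
            return float(offtake[a] + frac * (offtake[a + 1] - offtake[a]))
    return np.nan


def _first_upward_crossing(offtake: np.ndarray, values: np.ndarray,
                           level: float) -> float:
    if values[0] >= level:
        return float(offtake[0])
    for a in range(len(values) - 1):
        if values[a] < level <= values[a + 1]:
            frac = (level - values[a]) / (values[a + 1] - values[a])
            return float(offtake[a] + frac * (offtake[a + 1] - offtake[a]))
    return np.nan


def zero_growth_frontier(fit: SurfaceFit) -> tuple[pd.DataFrame, float]:
    """Per-phi offtake threshold where predicted growth crosses zero, plus
    the global frontier (the maximum over phi; 0 when growth is negative
    everywhere).

    Below the threshold the smoothed surface predicts positive growth; a
    phi whose predicted growth is non-positive even without offtake gets a
    NaN threshold.
    """
    if fit.family != "gaussian":
        raise ValueError("zero-growth frontier requires a gaussian-family growth fit")
    rows = []
    for phi in fit.phi_values:
        prof = fit.profile(phi)
        th = _first_downward_crossing(prof["offtake"].to_numpy(),
                                      prof["predicted"].to_numpy(), 0.0)
        rows.append({"phi": phi, "zero_growth_offtake": th})
    table = pd.DataFrame(rows)
    finite = table["zero_growth_offtake"].dropna()
    global_frontier = float(finite.max()) if len(finite) else 0.0
    return table, global_frontier


def probability_contour(fit: SurfaceFit, level: float) -> pd.DataFrame:
    """Per-phi offtake at which predicted extinction probability first
    reaches ``level`` (linear interpolation; NaN if never reached)."""
    if fit.family != "binomial":
        raise ValueError("probability contours require a binomial-family fit")
    if not 0.0 < level < 1.0:
        raise ValueError(f"contour level must be in (0, 1), got {level}")
    rows = []
    for phi in fit.phi_values:
        prof = fit.profile(phi)
        th = _first_upward_crossing(prof["offtake"].to_numpy(),
                                    prof["predicted"].to_numpy(), level)
        rows.append({"phi": phi, "offtake": th})
    return pd.DataFrame(rows)


def empirical_zero_growth_frontier(summary: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Raw-grid analogue of the zero-growth frontier: interpolated crossing
    of the replicate-mean growth, no smoothing."""
    rows = []
    for phi, s in summary.groupby("phi", sort=True):
        s = s.sort_values("offtake")
        th = _first_downward_crossing(s["offtake"].to_numpy(),
                                      s["mean_growth_total"].to_numpy(), 0.0)
        rows.append({"phi": phi, "zero_growth_offtake": th})
    table = pd.DataFrame(rows)
    finite = table["zero_growth_offtake"].dropna()
    return table, float(finite.max()) if len(finite) else 0.0


def empirical_extinction_threshold(summary: pd.DataFrame,
                                   level: float = 1.0) -> pd.DataFrame:
    """Per-phi smallest offtake whose raw extinction probability reaches
    ``level`` (default: certain extinction)."""
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must be in (0, 1], got {level}")
    rows = []
    for phi, s in summary.groupby("phi", sort=True):
        s = s.sort_values("offtake")
        hit = s.loc[s["extinction_probability"] >= level, "offtake"]
        rows.append({"phi": phi,
                     "offtake": float(hit.iloc[0]) if len(hit) else np.nan})
    return pd.DataFrame(rows)


def k_sensitivity(
    params: DemographicParams,
    K_values: Sequence[int],
    grid: ScenarioGrid,
    *,
    smoother: str = "tensor",
    basis_dim: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Recompute the harvesting thresholds under alternative carrying
    capacities and report the largest shift.

    Returns a table with one row per K (global zero-growth frontier and the
    0.9-extinction-probability contour at the largest phi) plus a dict of
    the maximum absolute threshold shifts across K values.
    """
    K_values = list(K_values)
    if len(K_values) < 2:
        raise ValueError("K sensitivity needs at least two K values")
    rows = []
    for K in K_values:
        records = run_grid(grid, replace(params, K=int(K)))
        gfit = fit_metric_surface(records, "growth_total", "gaussian",
                                  smoother=smoother, basis_dim=basis_dim)
        _, frontier = zero_growth_frontier(gfit)
        efit = fit_metric_surface(records, "extinct", "binomial",
                                  smoother=smoother, basis_dim=basis_dim)
        contour = probability_contour(efit, 0.9)
        phi_max = contour["phi"].max()
        p90 = float(contour.loc[contour["phi"] == phi_max, "offtake"].iloc[0])
        rows.append({"K": int(K), "zero_growth_frontier": frontier,
                     "p90_offtake_at_phi_max": p90})
    table = pd.DataFrame(rows)
    shifts = {
        "zero_growth_frontier": float(np.ptp(table["zero_growth_frontier"].to_numpy())),
        "p90_offtake_at_phi_max": float(np.ptp(table["p90_offtake_at_phi_max"].to_numpy())),
    }
    return table, shifts


def export_surface(fit: SurfaceFit, out_dir: Path | str, stem: str) -> None:
    """Write the prediction grid CSV and fit-provenance JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit.grid.to_csv(out_dir / f"{stem}_predictions.csv", index=False)
    (out_dir / f"{stem}_fit.json").write_text(
        json.dumps({"metric": fit.metric, "family": fit.family,
                    "smoother": fit.smoother}, indent=2))
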
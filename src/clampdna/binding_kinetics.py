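"""Equilibrium binding and coupled-assay kinetics.

Two small, self-contained fits used throughout clamp-loader
biochemistry:

* one-site anisotropy binding, Y = Bmax X / (Kd + X), by nonlinear
  least squares with curvature-based standard errors; and
* ATPase rates from NADH-depletion timecourses (pyruvate kinase /
  lactate dehydrogenase coupled assay, absorbance at 340 nm): the
  ordinary-least-squares slope over a fit window (default 100-500 s),
  converted to µM ATP/s via the NADH extinction coefficient assuming
  1:1 NADH:ADP stoichiometry, and normalized relative to a reference
  condition whose rate is scaled to exactly one.

No ligand-depletion (quadratic) correction is applied: the simple
hyperbola is the model fit here.  Relative rates are independent of the
extinction coefficient and optical pathlength, which is why they are
the robust cross-condition quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationDataset",
    "BindingFit",
    "FoldChange",
    "Timecourse",
    "RateMeasurement",
    "DegenerateDataError",
    "NormalizationError",
    "fit_one_site",
    "compare_fits",
    "rate_from_timecourse",
    "relative_rates",
    "read_titration_csv",
    "read_timecourse_csv",
]

NADH_EXTINCTION = 6220.0   # M^-1 cm^-1 at 340 nm


class DegenerateDataError(ValueError):
    """Data carry no signal the model could fit."""


class NormalizationError(ValueError):
    """Reference rate unusable for normalization."""


@dataclass
class TitrationDataset:
    """Titrant concentrations (nM) vs anisotropy change."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if len(self.x) < 4:
            raise ValueError("need at least 4 titration points")
        if np.any(self.x < 0):
            raise ValueError("negative titrant concentration")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("titrant concentrations must be strictly increasing")


@dataclass
class BindingFit:
    kd: float                  # nM
    bmax: float                # anisotropy units
    kd_se: float
    bmax_se: float
    rss: float
    converged: bool
    n: int
    label: str = ""


@dataclass
class FoldChange:
    ratio: float
    se: float


@dataclass
class Timecourse:
    """An A340-vs-time trace with reaction metadata."""

    t: np.ndarray
    a340: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.t.shape != self.a340.shape or self.t.ndim != 1:
            raise ValueError("t and a340 must be 1-d arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")


@dataclass
class RateMeasurement:
    slope: float               # AU/s over the fit window
    slope_se: float
    window: tuple[float, float]
    rate: float                # µM ATP/s
    label: str = ""
    relative_rate: float | None = None


def _one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * x / (kd + x)


# deterministic multiplicative jitters for the restart strategy
_RESTART_JITTERS = ((1.0, 1.0), (0.3, 1.0), (3.0, 1.0))


def fit_one_site(d: TitrationDataset,
                 init: tuple[float, float] | None = None) -> BindingFit:
    """Fit Y = Bmax X / (Kd + X) by nonlinear least squares.

    Initialization defaults to Bmax0 = max(Y) and Kd0 = the X nearest
    half-maximal Y; the fit is rerun from three deterministically
    jittered starts and the lowest residual sum of squares kept.
    Standard errors come from the local curvature (covariance) at the
    optimum.  Non-convergence is reported via ``converged=False`` with
    NaN parameters, never silently.
    """
    x, y = d.x, d.y
    if np.ptp(y) == 0:
        raise DegenerateDataError(
            "anisotropy values are all identical; nothing to fit")
    if np.allclose(y, 0):
        raise DegenerateDataError("anisotropy values are all zero")

    if init is not None:
        bmax0, kd0 = float(init[1]), float(init[0])
    else:
        bmax0 = float(np.max(y))
        half = bmax0 / 2.0
        kd0 = float(x[np.argmin(np.abs(y - half))])
        kd0 = max(kd0, float(np.min(x[x > 0], initial=1.0)) * 1e-3, 1e-9)

    best = None
    for jk, jb in _RESTART_JITTERS:
        try:
            popt, pcov = curve_fit(
                _one_site, x, y, p0=[bmax0 * jb, kd0 * jk],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=10_000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_one_site(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.inf,
                          converged=False, n=len(x), label=d.label)
    popt, pcov, rss = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 2
    return BindingFit(kd=float(popt[1]), bmax=float(popt[0]),
                      kd_se=float(perr[1]), bmax_se=float(perr[0]),
                      rss=rss, converged=True, n=len(x), label=d.label)


def compare_fits(a: BindingFit, b: BindingFit) -> FoldChange:
    """Kd fold change b/a with uncertainty propagated from the fit SEs.

    A ratio > 1 means condition ``b`` binds more weakly than ``a``.
    """
    for fit, name in ((a, "a"), (b, "b")):
        if not fit.converged:
            raise ValueError(f"fit {name!r} did not converge")
    ratio = b.kd / a.kd
    rel = np.sqrt((a.kd_se / a.kd) ** 2 + (b.kd_se / b.kd) ** 2)
    return FoldChange(ratio=float(ratio), se=float(ratio * rel))


def rate_from_timecourse(tc: Timecourse,
                         window: tuple[float, float] = (100.0, 500.0),
                         extinction: float = NADH_EXTINCTION,
                         pathlength: float = 1.0,
                         min_points: int = 10) -> RateMeasurement:
    """ATP turnover rate from the linear A340 decay within a window.

    Ordinary least squares of A340 vs t over the closed window; the
    rate is -slope / (extinction * pathlength), converted to µM/s with
    1:1 NADH:ADP stoichiometry.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window start must precede window end")
    if t0 < tc.t[0] or t1 > tc.t[-1]:
        raise ValueError(f"window {window} outside data range "
                         f"[{tc.t[0]}, {tc.t[-1]}]")
    mask = (tc.t >= t0) & (tc.t <= t1)
    if int(mask.sum()) < min_points:
        raise ValueError(f"need >= {min_points} points inside the window, "
                         f"got {int(mask.sum())}")
    t, a = tc.t[mask], tc.a340[mask]
    n = len(t)
    tbar = t.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (a - a.mean())) / sxx)
    intercept = float(a.mean() - slope * tbar)
    resid = a - (intercept + slope * t)
    s2 = float(np.sum(resid ** 2) / (n - 2)) if n > 2 else 0.0
    slope_se = float(np.sqrt(s2 / sxx))
    rate = -slope / (extinction * pathlength) * 1e6   # M/s -> µM/s
    return RateMeasurement(slope=slope, slope_se=slope_se, window=(t0, t1),
                           rate=rate, label=tc.label)


def relative_rates(measurements: list[RateMeasurement],
                   reference: str) -> pd.DataFrame:
    """Normalize rates to a reference condition (reference row = 1 exactly)."""
    by_label = {m.label: m for m in measurements}
    if reference not in by_label:
        raise KeyError(f"reference condition {reference!r} not among "
                       f"{sorted(by_label)}")
    ref_rate = by_label[reference].rate
    if ref_rate <= 0:
        raise NormalizationError(
            f"reference rate {ref_rate} is not positive; cannot normalize")
    rows = []
    for m in measurements:
        m.relative_rate = m.rate / ref_rate
        rows.append({"condition": m.label, "slope_AU_per_s": m.slope,
                     "rate_uM_per_s": m.rate, "relative_rate": m.relative_rate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _read_two_column(path, colnames) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("#").partition("=")
                meta[key.strip()] = val.strip()
            continue
        data_lines.append(line)
    sep = "\t" if ("\t" in data_lines[0]) else ","
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(data_lines)), sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two delimited columns")
    return (df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), meta)


def read_titration_csv(path, label: str = "") -> TitrationDataset:
    """Two-column (concentration, anisotropy) CSV/TSV; ``# key = value``
    header lines become metadata."""
    x, y, meta = _read_two_column(path, ("x", "y"))
    return TitrationDataset(x=x, y=y, label=label or meta.get("label", ""),
                            metadata=meta)


def read_timecourse_csv(path, label: str = "") -> Timecourse:
    """Two-column (time s, A340) CSV/TSV with optional metadata header."""
    t, a, meta = _read_two_column(path, ("t", "a340"))
    return Timecourse(t=t, a340=a, label=label or meta.get("label", ""),
                      metadata=meta)
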
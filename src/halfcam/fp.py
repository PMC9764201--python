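"""Fluorescence-polarization binding analysis.

Polarization of a fluorescein-labeled peptide rises as a binding partner
(CaM) is titrated in.  The classic readout is a hyperbolic fit
``Y = B X / (Kd + X)`` of the baseline-subtracted polarization versus
titrant concentration; with a 100 nM labeled probe and nanomolar
affinities a substantial fraction of the titrant is consumed by binding
(ligand depletion), so an exact quadratic (depletion-corrected) fit is
offered alongside, and the free titrant concentration can be computed
from the fractional saturation.  When binding is too tight to resolve
(saturation already complete at the lowest informative concentrations)
the data still carry an upper bound on Kd: the concentration at which the
signal reaches its plateau.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FPTitration",
    "FPFit",
    "polarization",
    "bound_fraction_depletion",
    "fit_hyperbolic",
    "free_titrant",
    "kd_upper_bound",
    "write_titration_csv",
    "read_titration_csv",
]


@dataclass(frozen=True)
class FPTitration:
    """Polarization readings versus total titrant at fixed labeled-probe conc."""

    labeled_conc: float
    titrant_total: np.ndarray
    polarization: np.ndarray
    replicate_sd: Optional[np.ndarray] = None
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.titrant_total, dtype=float)
        p = np.asarray(self.polarization, dtype=float)
        object.__setattr__(self, "titrant_total", t)
        object.__setattr__(self, "polarization", p)
        if self.replicate_sd is not None:
            object.__setattr__(self, "replicate_sd", np.asarray(self.replicate_sd, float))
            if self.replicate_sd.shape != t.shape:
                raise ValueError("replicate_sd must align with titrant_total")
        if t.shape != p.shape:
            raise ValueError("titrant_total and polarization must align")
        if np.any(t < 0):
            raise ValueError("titrant concentrations must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("titrant_total must be strictly increasing")


@dataclass(frozen=True)
class FPFit:
    b_max: float
    kd: float
    stderr_b: float
    stderr_kd: float
    baseline: float
    depletion: bool


def polarization(iv: float, ih: float, g: float = 1.0) -> float:
    """``P = (Iv - g Ih) / (Iv + g Ih)`` from vertical/horizontal intensities."""
    if g <= 0:
        raise ValueError("g factor must be positive")
    denom = iv + g * ih
    if denom <= 0:
        raise ValueError("total intensity must be positive")
    return (iv - g * ih) / denom


def bound_fraction_depletion(total: np.ndarray, labeled: float, kd: float) -> np.ndarray:
    """Exact fraction of labeled probe bound, accounting for titrant depletion.

    Root of ``[PL] = (T + L + Kd - sqrt((T + L + Kd)^2 - 4 T L)) / 2``
    divided by L.
    """
    t = np.asarray(total, dtype=float)
    s = t + labeled + kd
    disc = s * s - 4.0 * t * labeled
    bound = 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))
    return bound / labeled


def _baseline_subtract(t: FPTitration) -> tuple[np.ndarray, np.ndarray, float]:
    """Subtract the zero-titrant (free probe) polarization if measured."""
    x = t.titrant_total
    y = t.polarization
    baseline = 0.0
    if x[0] == 0.0:
        baseline = float(y[0])
        x, y = x[1:], y[1:] - baseline
    return x, y, baseline


def fit_hyperbolic(t: FPTitration, depletion: bool = False) -> FPFit:
    """Fit ``Y = B X / (Kd + X)`` (or its depletion-exact variant) to a titration.

    ``depletion=True`` replaces the hyperbola by ``Y = B * f_bound(X; L,
    Kd)`` with the exact quadratic bound fraction; the two agree when the
    labeled-probe concentration is far below Kd and diverge (hyperbolic
    Kd biased up by roughly L/2) for tight binders.
    """
    x, y, baseline = _baseline_subtract(t)
    if x.size < 4:
        raise ValueError("need at least 4 non-zero titrant points")
    # orientation check: signal must rise overall
    if y[-1] - y[0] <= 0 or np.polyfit(np.log(x), y, 1)[0] < 0:
        raise ValueError("polarization decreases with titrant: wrong assay orientation")

    if depletion:
        def model(xx, b, kd):
            return b * bound_fraction_depletion(xx, t.labeled_conc, kd)
    else:
        def model(xx, b, kd):
            return b * xx / (kd + xx)

    p0 = (float(y.max()), float(np.median(x)))
    sigma = None
    if t.replicate_sd is not None:
        sigma = t.replicate_sd[-x.size:]
    popt, pcov = curve_fit(model, x, y, p0=p0, sigma=sigma,
                           bounds=([0.0, 1e-15], [np.inf, np.inf]), maxfev=20000)
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return FPFit(b_max=float(popt[0]), kd=float(popt[1]),
                 stderr_b=float(perr[0]), stderr_kd=float(perr[1]),
                 baseline=baseline, depletion=depletion)


def free_titrant(total: float, labeled_conc: float, fractional_saturation: float):
    """Free titrant left in solution, ``total - labeled * saturation``, floored at 0."""
    if total < 0 or labeled_conc < 0 or fractional_saturation < 0:
        raise ValueError("inputs must be non-negative")
    free = np.asarray(total, dtype=float) - labeled_conc * fractional_saturation
    if np.any(free < 0):
        warnings.warn("bound exceeds total titrant; clipping free concentration at 0")
        free = np.maximum(free, 0.0)
    return free if free.ndim else float(free)


def kd_upper_bound(t: FPTitration, saturation_tol: float = 0.05) -> float:
    """Upper bound on Kd from the saturation concentration of the titration.

    A plateau is declared when the last three baseline-subtracted points
    lie within ``saturation_tol`` (relative) of each other; the plateau
    level is their mean, and the bound returned is the smallest
    titrant_total from which the signal is within tolerance of that
    level and stays there.  Returns ``math.inf`` ("unbounded") when no
    plateau is reached.  (The plateau is taken from the data rather than
    from the extrapolated hyperbolic maximum B, which systematically
    overshoots the reachable signal for depletion-regime binders and
    would then never declare saturation.)

    Note the structural floor of this rule: the bound fraction cannot
    exceed total/labeled, so the returned bound can never fall below
    ~``(1 - tol) * labeled_conc`` regardless of the true Kd.
    """
    x, y, _ = _baseline_subtract(t)
    if x.size < 4:
        raise ValueError("need at least 4 non-zero titrant points")
    tail = y[-3:]
    plateau_level = float(tail.mean())
    if plateau_level <= 0:
        return math.inf
    if np.any(np.abs(tail - plateau_level) > saturation_tol * plateau_level):
        return math.inf
    within = np.abs(y - plateau_level) <= saturation_tol * plateau_level
    # smallest concentration from which the signal stays within tolerance
    stays = np.logical_and.accumulate(within[::-1])[::-1]
    idx = int(np.argmax(stays))
    return float(x[idx])


# ------------------------------------------------------------------------- I/O


def write_titration_csv(t: FPTitration, path) -> None:
    header = f"# labeled_conc_M: {t.labeled_conc}\n# g_factor: {t.g_factor}\n"
    df = pd.DataFrame({"titrant_total_M": t.titrant_total, "polarization": t.polarization})
    if t.replicate_sd is not None:
        df["sd"] = t.replicate_sd
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_titration_csv(path) -> FPTitration:
    import io as _io

    meta, lines = {}, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = float(val)
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    return FPTitration(
        labeled_conc=meta["labeled_conc_M"],
        titrant_total=df["titrant_total_M"].to_numpy(),
        polarization=df["polarization"].to_numpy(),
        replicate_sd=df["sd"].to_numpy() if "sd" in df else None,
        g_factor=meta.get("g_factor", 1.0),
    )
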
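"""Isothermal titration calorimetry: forward model and isotherm fitting.

The forward model reproduces the per-injection heats of a perfusion-type
(overflow) calorimeter cell: each injection of volume v into a cell of
volume V0 displaces a fraction v/V0 of the cell content, so both the
titrand and the accumulated injectant are diluted by ``(1 - v/V0)`` per
injection.  Given the total titrand and injectant concentrations after
injection i, the bound injectant concentration is obtained from the
binding polynomial (closed-form quadratic for one class of sites, a
bracketed root solve on the monotone free-ligand equation for two
independent classes) and the heat of injection i is the enthalpy-weighted
change in bound moles in the cell, normalised per mole injected
(kcal / mol of injectant).

Fitting uses bounded trust-region least squares with the association
constant on a log scale (conditioning across 1e4..1e12 M-1); the first
data point of a measured isotherm is conventionally discarded because the
syringe dead volume makes the first delivered amount unreliable
(:func:`delete_first_injection`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationSchedule",
    "OneSiteParams",
    "TwoSiteParams",
    "Isotherm",
    "FitResult",
    "predicted_heats",
    "simulate_isotherm",
    "delete_first_injection",
    "fit_one_site",
    "fit_two_site",
    "apparent_kd",
    "write_isotherm_csv",
    "read_isotherm_csv",
]

_LOG_KA_BOUNDS = (np.log(1e3), np.log(1e13))


@dataclass(frozen=True)
class TitrationSchedule:
    """Volumes, concentrations and temperature of one titration.

    cell_volume (L), cell_conc (M, titrand in the cell), syringe_conc
    (M, injectant), n_injections, injection_volume (L), temperature (K).
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    n_injections: int
    injection_volume: float
    temperature: float

    def __post_init__(self) -> None:
        for name in ("cell_volume", "cell_conc", "syringe_conc", "injection_volume", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_injections < 2:
            raise ValueError("n_injections must be >= 2")

    @property
    def dilution_factor(self) -> float:
        return 1.0 - self.injection_volume / self.cell_volume

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Total titrand and injectant cell concentrations after each injection.

        Perfusion convention: M_i = M0 d^i and X_i = Xs (1 - d^i) with
        d = 1 - v/V0 (closed form of the per-injection dilution
        recursion X_i = X_{i-1} d + Xs (1 - d)).
        """
        i = np.arange(1, self.n_injections + 1)
        d = self.dilution_factor
        m_tot = self.cell_conc * d**i
        x_tot = self.syringe_conc * (1.0 - d**i)
        return m_tot, x_tot

    def molar_ratio(self) -> np.ndarray:
        """Cumulative injectant / titrand ratio after each injection."""
        m_tot, x_tot = self.totals()
        return x_tot / m_tot


@dataclass(frozen=True)
class OneSiteParams:
    """One class of ``n`` identical sites per titrand molecule.

    ka (M-1) is the per-site association constant; dh (kcal / mol of
    injectant bound) the binding enthalpy.
    """

    n: float
    ka: float
    dh: float

    def __post_init__(self) -> None:
        if self.n <= 0 or self.ka <= 0:
            raise ValueError("n and ka must be positive")

    @property
    def kd(self) -> float:
        return 1.0 / self.ka


@dataclass(frozen=True)
class TwoSiteParams:
    """Two independent classes of sites (vendor-convention two-site model)."""

    n1: float
    ka1: float
    dh1: float
    n2: float
    ka2: float
    dh2: float

    def __post_init__(self) -> None:
        if min(self.n1, self.n2) <= 0 or min(self.ka1, self.ka2) <= 0:
            raise ValueError("stoichiometries and association constants must be positive")

    def ordered(self) -> "TwoSiteParams":
        """Canonical label order: descending ka (removes swap degeneracy)."""
        if self.ka1 >= self.ka2:
            return self
        return TwoSiteParams(self.n2, self.ka2, self.dh2, self.n1, self.ka1, self.dh1)

    def classes(self) -> tuple[tuple[float, float, float], ...]:
        return ((self.n1, self.ka1, self.dh1), (self.n2, self.ka2, self.dh2))


Params = Union[OneSiteParams, TwoSiteParams]


@dataclass(frozen=True)
class Isotherm:
    """Per-injection normalised heats plus the schedule that produced them.

    ``injection_indices`` are 1-based injection numbers, so molar-ratio
    bookkeeping survives deletion of the first point.
    """

    schedule: TitrationSchedule
    heats: np.ndarray
    injection_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "heats", np.asarray(self.heats, dtype=float))
        object.__setattr__(self, "injection_indices", np.asarray(self.injection_indices, dtype=int))
        if self.heats.shape != self.injection_indices.shape:
            raise ValueError("heats and injection_indices must align")
        if self.heats.size == 0:
            raise ValueError("empty isotherm")

    @property
    def molar_ratio(self) -> np.ndarray:
        return self.schedule.molar_ratio()[self.injection_indices - 1]


@dataclass(frozen=True)
class FitResult:
    """Point estimates with asymptotic standard errors.

    ``stderr`` maps parameter names to standard errors (ka errors are
    delta-method transformed from the log scale).  ``converged`` is
    False when the optimiser failed or the association constant is
    unidentified (log-ka error > 5, i.e. more than two decades).
    """

    params: Params
    stderr: dict
    converged: bool
    cost: float
    message: str = ""


# ---------------------------------------------------------------- forward model


def _bound_one_class(m_tot: np.ndarray, x_tot: np.ndarray, n: float, ka: float) -> np.ndarray:
    """Bound injectant concentration for one class of sites (closed form)."""
    s = n * m_tot
    kd = 1.0 / ka
    b = s + x_tot + kd
    disc = b * b - 4.0 * s * x_tot
    bound = 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))
    return np.minimum(bound, np.minimum(s, x_tot))


def _bound_two_class(m_tot: np.ndarray, x_tot: np.ndarray, p: TwoSiteParams,
                     rtol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Per-class bound concentrations by root-finding the free-ligand equation.

    ``g(F) = F + sum_c n_c M ka_c F / (1 + ka_c F) - X`` is strictly
    increasing in F, so the root is bracketed by [0, X].
    """
    classes = p.classes()
    bound = np.zeros((2, len(x_tot)))
    for i, (m, x) in enumerate(zip(m_tot, x_tot)):
        if x == 0.0:
            continue

        def g(f: float) -> float:
            tot = f
            for n_c, ka_c, _ in classes:
                tot += n_c * m * ka_c * f / (1.0 + ka_c * f)
            return tot - x

        try:
            # xtol is absolute: scale it to the bracket so nanomolar roots
            # are still resolved to ~1e-15 relative
            free = brentq(g, 0.0, x, rtol=rtol, xtol=x * 1e-16, maxiter=200)
        except Exception as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"free-ligand root solve failed at X={x:.3e} M, M={m:.3e} M: {exc}"
            ) from exc
        for c, (n_c, ka_c, _) in enumerate(classes):
            bound[c, i] = n_c * m * ka_c * free / (1.0 + ka_c * free)
    return bound[0], bound[1]


def predicted_heats(params: Params, schedule: TitrationSchedule) -> np.ndarray:
    """Noise-free normalised heat of every injection (kcal / mol injected).

    Heat of injection i is ``V0 * sum_c dH_c * (B_c,i - d * B_c,i-1)``:
    the enthalpy-weighted change in bound moles, with the previous bound
    pool diluted by the displaced volume.
    """
    m_tot, x_tot = schedule.totals()
    d = schedule.dilution_factor
    v0 = schedule.cell_volume
    mol_injected = schedule.syringe_conc * schedule.injection_volume

    if isinstance(params, OneSiteParams):
        per_class = [(params.dh, _bound_one_class(m_tot, x_tot, params.n, params.ka))]
    else:
        b1, b2 = _bound_two_class(m_tot, x_tot, params)
        per_class = [(params.dh1, b1), (params.dh2, b2)]

    q = np.zeros(schedule.n_injections)
    for dh, bound in per_class:
        prev = np.concatenate(([0.0], bound[:-1]))
        q += v0 * dh * (bound - d * prev)
    return q / mol_injected


def simulate_isotherm(
    params: Params,
    schedule: TitrationSchedule,
    noise_sd: float = 0.1,
    seed: Optional[int] = None,
) -> Isotherm:
    """Simulate an isotherm with Gaussian heat noise (kcal / mol injected)."""
    heats = predicted_heats(params, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(schedule, heats, np.arange(1, schedule.n_injections + 1))


def delete_first_injection(iso: Isotherm) -> Isotherm:
    """Drop the earliest remaining injection, keeping molar-ratio bookkeeping."""
    if iso.heats.size < 2:
        raise ValueError("cannot delete the only remaining injection")
    return replace(iso, heats=iso.heats[1:], injection_indices=iso.injection_indices[1:])


# --------------------------------------------------------------------- fitting


def _model_at(iso: Isotherm, params: Params) -> np.ndarray:
    return predicted_heats(params, iso.schedule)[iso.injection_indices - 1]


def _cov_stderr(res, n_obs: int) -> np.ndarray:
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    cov = s2 * np.linalg.pinv(jtj)
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def fit_one_site(
    iso: Isotherm,
    init: Optional[OneSiteParams] = None,
    weights: Optional[np.ndarray] = None,
) -> FitResult:
    """Weighted least-squares fit of the one-class forward model.

    Non-convergence (including enthalpy-flat data, where ka is
    unidentifiable) is reported through ``converged=False`` rather than
    an exception.
    """
    if iso.heats.size < 5:
        raise ValueError("need at least 5 points to fit")
    if init is None:
        dh0 = float(iso.heats[np.argmax(np.abs(iso.heats))])
        init = OneSiteParams(n=1.0, ka=1e7, dh=dh0 if dh0 != 0 else -1.0)
    w = np.ones_like(iso.heats) if weights is None else np.asarray(weights, float)

    def resid(theta: np.ndarray) -> np.ndarray:
        p = OneSiteParams(n=theta[0], ka=np.exp(theta[1]), dh=theta[2])
        return w * (_model_at(iso, p) - iso.heats)

    x0 = np.array([init.n, np.log(init.ka), init.dh])
    lo = np.array([1e-3, _LOG_KA_BOUNDS[0], -np.inf])
    hi = np.array([20.0, _LOG_KA_BOUNDS[1], np.inf])
    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        x_scale=[1.0, 1.0, max(abs(init.dh), 1.0)])
    fitted = OneSiteParams(n=res.x[0], ka=float(np.exp(res.x[1])), dh=res.x[2])
    se = _cov_stderr(res, iso.heats.size)
    stderr = {"n": se[0], "ka": fitted.ka * se[1], "log_ka": se[1], "dh": se[2]}
    converged = bool(res.success) and se[1] < 5.0
    return FitResult(fitted, stderr, converged, float(res.cost), res.message)


def fit_two_site(
    iso: Isotherm,
    init: Optional[TwoSiteParams] = None,
    weights: Optional[np.ndarray] = None,
) -> FitResult:
    """Least-squares fit of two independent site classes.

    The returned classes are in canonical descending-ka order.  A
    ``message`` notes weak identifiability when the fitted association
    constants are within a factor of 3 of each other.
    """
    if iso.heats.size < 7:
        raise ValueError("need at least 7 points to fit two classes")
    if init is None:
        init = TwoSiteParams(0.5, 1e8, -5.0, 1.5, 1e7, -5.0)
    w = np.ones_like(iso.heats) if weights is None else np.asarray(weights, float)

    def resid(theta: np.ndarray) -> np.ndarray:
        p = TwoSiteParams(theta[0], np.exp(theta[1]), theta[2],
                          theta[3], np.exp(theta[4]), theta[5])
        return w * (_model_at(iso, p) - iso.heats)

    x0 = np.array([init.n1, np.log(init.ka1), init.dh1,
                   init.n2, np.log(init.ka2), init.dh2])
    lo = np.array([1e-3, _LOG_KA_BOUNDS[0], -np.inf] * 2)
    hi = np.array([20.0, _LOG_KA_BOUNDS[1], np.inf] * 2)
    res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    raw = TwoSiteParams(res.x[0], float(np.exp(res.x[1])), res.x[2],
                        res.x[3], float(np.exp(res.x[4])), res.x[5])
    se = _cov_stderr(res, iso.heats.size)
    err = {"n1": se[0], "log_ka1": se[1], "ka1": raw.ka1 * se[1], "dh1": se[2],
           "n2": se[3], "log_ka2": se[4], "ka2": raw.ka2 * se[4], "dh2": se[5]}
    fitted = raw.ordered()
    if fitted is not raw:  # swap labels in the error dict too
        err = {"n1": err["n2"], "log_ka1": err["log_ka2"], "ka1": err["ka2"], "dh1": err["dh2"],
               "n2": err["n1"], "log_ka2": err["log_ka1"], "ka2": err["ka1"], "dh2": err["dh1"]}
    msg = res.message
    ratio = max(fitted.ka1, fitted.ka2) / min(fitted.ka1, fitted.ka2)
    if ratio < 3.0:
        msg += " [warning: site classes overlap (ka ratio < 3), weakly identifiable]"
    converged = bool(res.success) and max(se[1], se[4]) < 5.0
    return FitResult(fitted, err, converged, float(res.cost), msg)


def apparent_kd(params: Params, expected_n: float = 2.0) -> float:
    """Apparent dissociation constant (M).

    One class: 1/ka.  Two classes: 1/ka of the stoichiometric (major)
    component, i.e. the class whose n is nearest ``expected_n``.
    """
    if isinstance(params, OneSiteParams):
        return params.kd
    classes = params.classes()
    n_maj, ka_maj, _ = min(classes, key=lambda c: abs(c[0] - expected_n))
    return 1.0 / ka_maj


# ------------------------------------------------------------------------- I/O


def write_isotherm_csv(iso: Isotherm, path) -> None:
    """Columnar CSV with the schedule in ``#`` header comments."""
    s = iso.schedule
    header = (
        f"# cell_volume_L: {s.cell_volume}\n"
        f"# cell_conc_M: {s.cell_conc}\n"
        f"# syringe_conc_M: {s.syringe_conc}\n"
        f"# n_injections: {s.n_injections}\n"
        f"# injection_volume_L: {s.injection_volume}\n"
        f"# temperature_K: {s.temperature}\n"
    )
    df = pd.DataFrame(
        {
            "injection_index": iso.injection_indices,
            "volume_L": np.full(iso.heats.size, s.injection_volume),
            "heat_kcal_per_mol": iso.heats,
        }
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_isotherm_csv(path) -> Isotherm:
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = float(val)
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    schedule = TitrationSchedule(
        cell_volume=meta["cell_volume_L"],
        cell_conc=meta["cell_conc_M"],
        syringe_conc=meta["syringe_conc_M"],
        n_injections=int(meta["n_injections"]),
        injection_volume=meta["injection_volume_L"],
        temperature=meta["temperature_K"],
    )
    return Isotherm(schedule, df["heat_kcal_per_mol"].to_numpy(),
                    df["injection_index"].to_numpy())
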
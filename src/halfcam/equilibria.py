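"""Coupled Ca2+ / calmodulin / IQ-motif equilibria.

Calmodulin (CaM) bound to the CaV1.2 IQ motif loads Ca2+ in two sequential
macroscopic steps: first the C-lobe (EF-hands 3+4), then the N-lobe
(EF-hands 1+2).  Each step binds ``n_per_step`` Ca2+ ions as a single
cooperative unit (default 2, one pair of EF-hands).  This module computes

* hyperbolic lobe occupancy ``Y = c / (c + KDapp)``,
* species fractions of apoCaM-IQ, Ca2/CaM-IQ and Ca4/CaM-IQ versus free
  Ca2+ from the two-step binding polynomial,
* apparent Ca2+ affinities from the thermodynamic linkage cycle (IQ
  binding shifts the Ca2+ affinity by the ratio of IQ affinities of the
  loaded and apo states),
* van't Hoff temperature scaling of a dissociation constant and the heat
  capacity change from enthalpies at two temperatures.

Concentrations are molar and temperatures kelvin throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_CAL",
    "BindingScheme",
    "LinkageCycle",
    "SpeciesFractions",
    "lobe_occupancy",
    "species_fractions",
    "species_fraction_profile",
    "apparent_kd_linkage",
    "vant_hoff_kd_ratio",
    "delta_cp",
    "celsius_to_kelvin",
]

#: Gas constant, cal mol-1 K-1.
R_CAL = 1.98720425


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) + 273.15


@dataclass(frozen=True)
class BindingScheme:
    """Two-step Ca2+ ladder of IQ-bound CaM.

    ``k1_app`` / ``k2_app`` are the apparent macroscopic association
    constants for Ca2+ loading of the C-lobe and N-lobe respectively, in
    units of M^-n where n = ``n_per_step``.
    """

    k1_app: float
    k2_app: float
    n_per_step: int = 2

    def __post_init__(self) -> None:
        if not (self.k1_app > 0 and self.k2_app > 0):
            raise ValueError("association constants must be positive")
        if int(self.n_per_step) < 1 or self.n_per_step != int(self.n_per_step):
            raise ValueError("n_per_step must be an integer >= 1")


@dataclass(frozen=True)
class LinkageCycle:
    """Thermodynamic cycle linking Ca2+ and IQ binding.

    ``kd_ca_free``: Ca2+ dissociation constant of a lobe of free CaM (M).
    ``kd_iq_apo`` / ``kd_iq_loaded``: IQ dissociation constants of the
    Ca2+-free and Ca2+-loaded lobe states (M).
    """

    kd_ca_free: float
    kd_iq_apo: float
    kd_iq_loaded: float

    def __post_init__(self) -> None:
        if not (self.kd_ca_free > 0 and self.kd_iq_apo > 0 and self.kd_iq_loaded > 0):
            raise ValueError("all dissociation constants must be positive")


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of apoCaM-IQ, Ca2/CaM-IQ and Ca4/CaM-IQ (sum to 1)."""

    f_apo: float
    f_ca2: float
    f_ca4: float

    def __post_init__(self) -> None:
        for f in (self.f_apo, self.f_ca2, self.f_ca4):
            if not (-1e-12 <= f <= 1 + 1e-12):
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.f_apo + self.f_ca2 + self.f_ca4 - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.f_apo, self.f_ca2, self.f_ca4)


def lobe_occupancy(ca_free: float, kd_app: float) -> float:
    """Fractional Ca2+ saturation of one lobe, ``Y = c / (c + KDapp)``."""
    if kd_app <= 0:
        raise ValueError("kd_app must be positive")
    if ca_free < 0:
        raise ValueError("ca_free must be non-negative")
    if math.isinf(ca_free):
        return 1.0
    return ca_free / (ca_free + kd_app)


def species_fractions(ca_free: float, scheme: BindingScheme) -> SpeciesFractions:
    """Partition the CaM-IQ pool among apo, half- and fully loaded states.

    The binding polynomial is ``Z = 1 + k1 c^n + k1 k2 c^(2n)`` with
    ``c`` the free Ca2+ concentration; the species weights are the three
    terms of Z.  Evaluated in log space so extreme constants do not
    overflow.
    """
    if ca_free < 0:
        raise ValueError("ca_free must be non-negative")
    if ca_free == 0:
        return SpeciesFractions(1.0, 0.0, 0.0)
    if math.isinf(ca_free):
        return SpeciesFractions(0.0, 0.0, 1.0)
    n = scheme.n_per_step
    logc = math.log(ca_free)
    logw = np.array(
        [
            0.0,
            math.log(scheme.k1_app) + n * logc,
            math.log(scheme.k1_app) + math.log(scheme.k2_app) + 2 * n * logc,
        ]
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    # renormalise exactly so the invariant holds to 1e-12
    f_apo, f_ca2 = float(w[0]), float(w[1])
    return SpeciesFractions(f_apo, f_ca2, 1.0 - f_apo - f_ca2)


def species_fraction_profile(ca_grid, scheme: BindingScheme):
    """Species fractions over a grid of free Ca2+ values.

    Returns a pandas DataFrame with columns ``ca_free_M, f_apo, f_ca2,
    f_ca4`` (the CSV layout written by the CLI).
    """
    import pandas as pd

    rows = [species_fractions(float(c), scheme).as_tuple() for c in np.asarray(ca_grid)]
    arr = np.array(rows)
    return pd.DataFrame(
        {
            "ca_free_M": np.asarray(ca_grid, dtype=float),
            "f_apo": arr[:, 0],
            "f_ca2": arr[:, 1],
            "f_ca4": arr[:, 2],
        }
    )


def apparent_kd_linkage(cycle: LinkageCycle) -> float:
    """Apparent Ca2+ KD of a lobe in the IQ-bound complex.

    Cycle closure gives ``KDapp = KD(Ca, free CaM) x KD(IQ, loaded) /
    KD(IQ, apo)``: tighter IQ binding to the loaded state (ratio < 1)
    raises the apparent Ca2+ affinity by the same factor.
    """
    return cycle.kd_ca_free * (cycle.kd_iq_loaded / cycle.kd_iq_apo)


def vant_hoff_kd_ratio(delta_h_kcal: float, t1_kelvin: float, t2_kelvin: float) -> float:
    """``KD(t2)/KD(t1)`` assuming a temperature-independent binding enthalpy.

    ``ln K_a = -dH/(R T) + dS/R`` gives ``KD(t2)/KD(t1) =
    exp[(dH/R) (1/t2 - 1/t1)]``; for exothermic binding (dH < 0) warming
    weakens binding, ratio > 1.
    """
    if t1_kelvin <= 0 or t2_kelvin <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    dh_cal = delta_h_kcal * 1000.0
    return math.exp((dh_cal / R_CAL) * (1.0 / t2_kelvin - 1.0 / t1_kelvin))


def delta_cp(
    delta_h_t1_kcal: float,
    delta_h_t2_kcal: float,
    t1_kelvin: float,
    t2_kelvin: float,
) -> float:
    """Heat capacity change, ``(dH(t2) - dH(t1)) / (t2 - t1)``, kcal mol-1 K-1."""
    if t1_kelvin == t2_kelvin:
        raise ValueError("t1 and t2 must differ")
    return (delta_h_t2_kcal - delta_h_t1_kcal) / (t2_kelvin - t1_kelvin)
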
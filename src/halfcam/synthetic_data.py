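"""Seeded generators for every input the analysis modules consume.

Each generator is a pure function of (parameters, seed), so the whole
pipeline is testable without instrument data.  Preset parameter sets in
:data:`PRESETS` encode the study conditions the package is built around:
the published ITC fit parameters and titration schedules for Ca2+
binding to the CaM12'-IQ complex and for Ca2/CaM12' binding to IQ
variants, the fluorescence-polarization regimes (100 nM labeled
peptide; the weak Y1657D/apoCaM binder at 60 uM and the tight wild-type
binder at 16 nM), the whole-cell protocol (900 ms steps, -60..+50 mV in
10 mV increments, Ba2+ vs the faster-inactivating Ca2+), and the
cell-attached protocol (2 s depolarizations sampled at 10 kHz through a
2 kHz low-pass filter).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import ephys_singlechannel as sc
from . import ephys_wholecell as wc
from . import fp as fp_mod
from . import itc as itc_mod
from . import structure_metrics as sm

__all__ = [
    "PRESETS",
    "gen_itc",
    "gen_fp",
    "gen_wholecell",
    "gen_singlechannel",
    "gen_ensemble",
]


def _sched(cell_conc, syringe_conc, temperature):
    return itc_mod.TitrationSchedule(
        cell_volume=1.5e-3,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        n_injections=35,
        injection_volume=10e-6,
        temperature=temperature,
    )


#: Study-condition presets.  ITC entries carry (params, schedule); FP
#: entries the generating constants and titrant grid; ephys entries the
#: pulse protocols.  Noise defaults: 0.1 kcal/mol of injectant for ITC
#: heats, 5%/3% of the FP plateau, 5 pA whole-cell, SNR 5 single-channel.
PRESETS: dict = {
    "itc": {
        # Ca2+ titrated into the CaM12'-IQ complex
        "ca_cam12_iq_37C": {
            "params": itc_mod.OneSiteParams(n=1.8, ka=1.4e7, dh=-7.7),
            "schedule": _sched(8e-6, 0.30e-3, 310.15),
            "noise_sd": 0.1,
        },
        "ca_cam12_iq_27C": {
            "params": itc_mod.TwoSiteParams(n1=0.2, ka1=6e8, dh1=-10.0,
                                            n2=1.7, ka2=1.7e7, dh2=-7.5),
            "schedule": _sched(10e-6, 0.23e-3, 300.15),
            "noise_sd": 0.1,
        },
        # Ca2/CaM12' titrated into IQ peptide variants
        "wt27": {
            "params": itc_mod.OneSiteParams(n=0.77, ka=1.0 / 16e-9, dh=-10.0),
            "schedule": _sched(10e-6, 0.1e-3, 300.15),
            "noise_sd": 0.1,
        },
        "wt37": {
            "params": itc_mod.OneSiteParams(n=0.76, ka=1.0 / 37e-9, dh=-15.0),
            "schedule": _sched(7e-6, 0.1e-3, 310.15),
            "noise_sd": 0.1,
        },
        "y1657d27": {
            "params": itc_mod.OneSiteParams(n=0.72, ka=1.0 / 8000e-9, dh=-5.6),
            "schedule": _sched(50e-6, 0.5e-3, 300.15),
            "noise_sd": 0.1,
        },
    },
    "fp": {
        # apoCaM titrated into the weakened Y1657D IQ peptide
        "y1657d_apocam": {
            "kd": 60e-6,
            "b_max": 0.2,
            "labeled_conc": 100e-9,
            "grid": np.logspace(np.log10(0.5e-6), np.log10(500e-6), 12),
            "noise_sd": 0.01,  # 5% of B
            "depletion": False,
        },
        # Ca2/CaM12' titrated into wild-type IQ: tight binder, depletion regime
        "wt_tight": {
            "kd": 16e-9,
            "b_max": 0.2,
            "labeled_conc": 100e-9,
            "grid": np.logspace(np.log10(10e-9), np.log10(1000e-9), 12),
            "noise_sd": 0.006,  # 3% of plateau
            "depletion": True,
        },
    },
    "wholecell": {
        "strong-CDI": {
            "ba_tau": {"a_fast": 0.25, "tau_fast_ms": 200.0, "tau_slow_ms": 3000.0},
            "ca_tau": {"a_fast": 0.75, "tau_fast_ms": 45.0, "tau_slow_ms": 800.0},
            "capacitance_pF": 20.0,
            "gmax_pA_per_mV": 12.0,
            "v_rev_mV": 55.0,
            "v_half_mV": -5.0,
            "k_slope_mV": 6.0,
            "noise_sd_pA": 0.0,
        },
    },
    "singlechannel": {
        "cell-attached": {
            "duration_s": 2.0,
            "sampling_rate_Hz": 10_000.0,
            "filter_cutoff_Hz": 2_000.0,
            "unitary_pA": -1.2,
            "close_rate_s": 50.0,
        },
    },
}


def gen_itc(preset: Optional[str] = None, params=None, schedule=None,
            noise_sd: float = 0.1, seed: Optional[int] = None) -> itc_mod.Isotherm:
    """Simulate an ITC isotherm from a preset name or explicit parameters."""
    if preset is not None:
        cfg = PRESETS["itc"][preset]
        params, schedule, noise_sd = cfg["params"], cfg["schedule"], cfg["noise_sd"]
    return itc_mod.simulate_isotherm(params, schedule, noise_sd=noise_sd, seed=seed)


def gen_fp(preset: Optional[str] = None, kd: float = None, b_max: float = 0.2,
           labeled_conc: float = 100e-9, grid=None, noise_sd: float = 0.0,
           depletion: bool = True, baseline: float = 0.05,
           seed: Optional[int] = None) -> fp_mod.FPTitration:
    """Simulate an FP titration.

    ``depletion=True`` generates from the exact quadratic bound fraction;
    ``depletion=False`` generates from the hyperbola ``Y = B X / (Kd + X)``
    (appropriate when the labeled probe is far below Kd).  A zero-titrant
    baseline point is prepended so fits can subtract the free-probe
    polarization.
    """
    if preset is not None:
        cfg = PRESETS["fp"][preset]
        kd, b_max = cfg["kd"], cfg["b_max"]
        labeled_conc, grid = cfg["labeled_conc"], cfg["grid"]
        noise_sd, depletion = cfg["noise_sd"], cfg["depletion"]
    grid = np.asarray(grid, dtype=float)
    if depletion:
        frac = fp_mod.bound_fraction_depletion(grid, labeled_conc, kd)
    else:
        frac = grid / (kd + grid)
    y = baseline + b_max * frac
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    titrant = np.concatenate(([0.0], grid))
    pol = np.concatenate(([baseline], y))
    return fp_mod.FPTitration(labeled_conc=labeled_conc, titrant_total=titrant,
                              polarization=pol)


def _biexp(t_ms: np.ndarray, a_fast: float, tau_fast_ms: float, tau_slow_ms: float
           ) -> np.ndarray:
    return a_fast * np.exp(-t_ms / tau_fast_ms) + (1.0 - a_fast) * np.exp(-t_ms / tau_slow_ms)


def gen_wholecell(preset: str = "strong-CDI", sampling_rate: float = 10_000.0,
                  pulse_ms: float = 900.0, activation_tau_ms: float = 0.0,
                  seed: Optional[int] = None
                  ) -> tuple[wc.WholeCellRecording, wc.WholeCellRecording]:
    """Paired Ba2+/Ca2+ whole-cell families, -60..+50 mV in 10 mV steps.

    Peak amplitude follows a Boltzmann-activated linear driving force
    ``I(V) = Gmax (V - Vrev) / (1 + exp(-(V - V1/2)/k))``; each sweep
    decays bi-exponentially from its peak, with the Ca2+ carrier's
    faster fast component encoding CDI.  ``activation_tau_ms = 0`` makes
    the peak sit exactly at depolarization onset so r300 has a closed
    form.
    """
    cfg = PRESETS["wholecell"][preset]
    rng = np.random.default_rng(seed)
    t_ms = np.arange(int(round(pulse_ms / 1000.0 * sampling_rate))) / sampling_rate * 1000.0
    potentials = np.arange(-60.0, 51.0, 10.0)
    recs = []
    for carrier in ("Ba", "Ca"):
        tau = cfg["ba_tau"] if carrier == "Ba" else cfg["ca_tau"]
        sweeps = {}
        for v in potentials:
            drive = cfg["gmax_pA_per_mV"] * (v - cfg["v_rev_mV"])
            act = 1.0 / (1.0 + np.exp(-(v - cfg["v_half_mV"]) / cfg["k_slope_mV"]))
            peak = drive * act  # negative below Vrev
            trace = peak * _biexp(t_ms, **tau)
            if activation_tau_ms > 0:
                trace = trace * (1.0 - np.exp(-t_ms / activation_tau_ms))
            if cfg["noise_sd_pA"] > 0:
                trace = trace + rng.normal(0.0, cfg["noise_sd_pA"], size=trace.shape)
            sweeps[float(v)] = trace
        recs.append(wc.WholeCellRecording(
            sweeps=sweeps, capacitance=cfg["capacitance_pF"], carrier=carrier,
            sampling_rate=sampling_rate, pulse_duration=pulse_ms))
    return recs[0], recs[1]


def gen_singlechannel(p_open: float, n_channels: int, n_sweeps: int,
                      preset: str = "cell-attached", noise_sd: Optional[float] = None,
                      seed: Optional[int] = None) -> tuple[sc.GatingModel, sc.SweepSet]:
    """Simulate cell-attached sweeps at a target P_o with the standard protocol."""
    cfg = PRESETS["singlechannel"][preset]
    model = sc.GatingModel.from_po(p_open, cfg["close_rate_s"], cfg["unitary_pA"],
                                   n_channels)
    if noise_sd is None:
        noise_sd = abs(cfg["unitary_pA"]) / 5.0  # SNR 5
    sweeps = sc.simulate_sweeps(model, n_sweeps, cfg["duration_s"],
                                cfg["sampling_rate_Hz"], noise_sd,
                                cfg["filter_cutoff_Hz"], seed=seed)
    return model, sweeps


def gen_ensemble(n_models: int = 10, jitter_sd: float = 0.5, n_residues: int = 30,
                 seed: Optional[int] = None) -> sm.Ensemble:
    """Synthetic NMR-style ensemble: a rigid scaffold plus Gaussian jitter.

    The scaffold is an idealised poly-alanine-like backbone (N, CA, C, O
    per residue on a helical path); every model adds isotropic Gaussian
    coordinate jitter of SD ``jitter_sd`` (A), giving a known expected
    RMSD to the mean structure.
    """
    rng = np.random.default_rng(seed)
    res_ids, names, coords = [], [], []
    rise, twist, radius = 1.5, np.deg2rad(100.0), 2.3
    offsets = {"N": (-0.5, -0.4), "CA": (0.0, 0.0), "C": (0.5, 0.4), "O": (0.7, 1.3)}
    for r in range(1, n_residues + 1):
        phi0 = r * twist
        for name in ("N", "CA", "C", "O"):
            dphi, dz = offsets[name]
            phi = phi0 + dphi
            coords.append([radius * np.cos(phi), radius * np.sin(phi), r * rise + dz])
            res_ids.append(r)
            names.append(name)
    scaffold = np.array(coords)
    models = []
    for _ in range(n_models):
        jitter = rng.normal(0.0, jitter_sd, size=scaffold.shape) if jitter_sd > 0 else 0.0
        models.append(sm.Model(np.array(res_ids), list(names), scaffold + jitter))
    return sm.Ensemble(models)
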
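"""Whole-cell current analysis: I/V curves, r300, CDI (f300) and VDI.

Conventions: inward current is negative in the traces; metrics are
computed on magnitudes.  The inactivation clock starts at depolarization
onset (sample 0 of each sweep), not at the time of peak current, so
``r300`` is the current remaining 300 ms after the start of the pulse
divided by the peak current within the pulse.  CDI is read out as
``f300 = r300(Ba) - r300(Ca)``: with Ba2+ as charge carrier only
voltage-dependent inactivation (VDI, ``1 - r300(Ba)``) operates, while
Ca2+ adds the calcium-dependent component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

__all__ = [
    "WholeCellRecording",
    "IVCurve",
    "peak_current_density",
    "normalize_to_imax",
    "r300",
    "cdi_f300",
    "vdi",
    "write_recording",
    "read_recording",
]


@dataclass
class WholeCellRecording:
    """A family of test-potential sweeps from one cell.

    ``sweeps`` maps test potential (mV) to the current trace (pA) sampled
    at ``sampling_rate`` (Hz) from depolarization onset.
    """

    sweeps: Dict[float, np.ndarray]
    capacitance: float  # pF
    carrier: str  # "Ba" or "Ca"
    sampling_rate: float  # Hz
    pulse_duration: float  # ms
    holding: float = -80.0  # mV

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.carrier not in ("Ba", "Ca"):
            raise ValueError("carrier must be 'Ba' or 'Ca'")
        self.sweeps = {float(v): np.asarray(tr, dtype=float) for v, tr in self.sweeps.items()}


@dataclass
class IVCurve:
    potentials: np.ndarray
    peak_density: np.ndarray  # pA/pF, signed (inward negative)
    imax_potential: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.peak_density = np.asarray(self.peak_density, dtype=float)
        if self.potentials.shape != self.peak_density.shape:
            raise ValueError("potentials and peak_density must align")


def peak_current_density(rec: WholeCellRecording) -> IVCurve:
    """Peak inward current per potential, divided by cell capacitance."""
    if not rec.sweeps:
        raise ValueError("recording has no sweeps")
    pot = np.array(sorted(rec.sweeps))
    dens = np.empty_like(pot)
    for i, v in enumerate(pot):
        tr = rec.sweeps[v]
        if tr.size == 0:
            raise ValueError(f"empty sweep at {v} mV")
        dens[i] = tr.min() / rec.capacitance  # inward negative
    imax_pot = float(pot[np.argmax(np.abs(dens))]) if np.any(dens) else np.nan
    return IVCurve(pot, dens, imax_pot)


def normalize_to_imax(values: np.ndarray) -> np.ndarray:
    """Divide by |I_max| so the largest-magnitude entry has magnitude 1."""
    v = np.asarray(values, dtype=float)
    imax = np.abs(v).max()
    if imax == 0:
        raise ValueError("all-zero input cannot be normalized")
    return v / imax


def r300(
    trace: np.ndarray,
    sampling_rate: float,
    window_ms: float = 5.0,
    t_ms: float = 300.0,
) -> float:
    """Fraction of peak current remaining ``t_ms`` after depolarization onset.

    The remaining current is a mean over a ``window_ms`` window centred
    at ``t_ms`` (default 5 ms at 300 ms); the peak is the largest
    magnitude up to ``t_ms``.  Values > 1 (facilitating traces, where
    the current keeps growing past the peak window) are permitted but
    flagged with a warning.
    """
    tr = np.asarray(trace, dtype=float)
    n300 = int(round(t_ms / 1000.0 * sampling_rate))
    if tr.size <= n300:
        raise ValueError(f"trace must cover at least {t_ms} ms after onset")
    half = int(round(window_ms / 2000.0 * sampling_rate))
    head = tr[: max(n300 - half, 1)]
    peak = head[np.argmax(np.abs(head))]
    if peak == 0:
        raise ValueError("zero peak current")
    lo, hi = max(n300 - half, 0), min(n300 + half + 1, tr.size)
    remaining = tr[lo:hi].mean()
    r = abs(remaining) / abs(peak)
    if r > 1.0:
        warnings.warn(f"r300 = {r:.3f} > 1: facilitating trace")
    return float(r)


def cdi_f300(r_ba300: float, r_ca300: float) -> float:
    """CDI readout ``f300 = r300(Ba) - r300(Ca)``; negative values flagged."""
    for r in (r_ba300, r_ca300):
        if not (0.0 <= r <= 1.2):
            raise ValueError("r300 values must lie in [0, ~1.2]")
    f = r_ba300 - r_ca300
    if f < 0:
        warnings.warn("negative f300: Ca2+ inactivating slower than Ba2+ is nonphysical here")
    return f


def vdi(r_ba300: float) -> float:
    """Voltage-dependent inactivation, ``1 - r300(Ba)``."""
    if not (0.0 <= r_ba300 <= 1.2):
        raise ValueError("r300 must lie in [0, ~1.2]")
    return 1.0 - r_ba300


# ------------------------------------------------------------------------- I/O


def write_recording(rec: WholeCellRecording, path) -> None:
    """Columnar text: time_s then one column per test potential (mV)."""
    pot = sorted(rec.sweeps)
    n = len(rec.sweeps[pot[0]])
    data = {"time_s": np.arange(n) / rec.sampling_rate}
    for v in pot:
        data[f"{v:g}"] = rec.sweeps[v]
    header = (
        f"# capacitance_pF: {rec.capacitance}\n"
        f"# carrier: {rec.carrier}\n"
        f"# sampling_rate_Hz: {rec.sampling_rate}\n"
        f"# pulse_duration_ms: {rec.pulse_duration}\n"
        f"# holding_mV: {rec.holding}\n"
        "# sign_convention: inward_negative\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(data).to_csv(fh, index=False)


def read_recording(path) -> WholeCellRecording:
    import io as _io

    meta, lines = {}, []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    sweeps = {float(c): df[c].to_numpy() for c in df.columns if c != "time_s"}
    return WholeCellRecording(
        sweeps=sweeps,
        capacitance=float(meta["capacitance_pF"]),
        carrier=meta["carrier"],
        sampling_rate=float(meta["sampling_rate_Hz"]),
        pulse_duration=float(meta["pulse_duration_ms"]),
        holding=float(meta.get("holding_mV", -80.0)),
    )
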
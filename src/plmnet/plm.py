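"""Phase linearity measurement (PLM) connectivity.

The PLM quantifies phase synchronization between two band-limited signals
as the fraction of the spectral energy of the interferometric signal
``z(t) = exp(i * (phi_i(t) - phi_j(t)))`` that is concentrated within a
narrow band ``|f| <= B`` around zero frequency:

    PLM = sum_{|f| <= B} |S_z(f)|^2 / sum_f |S_z(f)|^2

where ``S_z(f)`` is the spectrum of ``z`` — ``|S_z(f)|^2`` is its
spectral energy density (the periodogram).  If the phase
difference evolves linearly in time (a constant frequency offset between
the two oscillators), ``z`` is a single spectral line and the PLM is 1;
if the phase difference wanders broadband, the PLM drops toward 0.

The f = 0 bin is zeroed by default (``discard_dc``): an identically-zero
phase difference — the signature of one signal leaking instantaneously
into both regions (volume conduction) — then contributes nothing, which is
what makes the metric insensitive to instantaneous mixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .signal import PhaseSeries

__all__ = ["PlmConfig", "ConnectivityMatrix", "plm_pair", "plm_matrix"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlmConfig:
    """Parameters of the PLM estimator.

    B : half-bandwidth of the integration band in Hz (default 1).
    spectral_estimator : 'periodogram' (deterministic, parameter-free,
        default) or 'welch' (averaged modified periodograms, more noise
        resilient, coarser frequency resolution).
    welch_segment_s : Welch segment length in seconds; must resolve the
        integration band (>= 2 / B).
    discard_dc : zero the f = 0 bin before integrating (volume-conduction
        guard); on by default.
    """

    B: float = 1.0
    spectral_estimator: str = "periodogram"
    welch_segment_s: float = 4.0
    discard_dc: bool = True

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("integration half-bandwidth B must be positive")
        if self.spectral_estimator not in ("periodogram", "welch"):
            raise ValueError(f"unknown spectral estimator {self.spectral_estimator!r}")
        if self.spectral_estimator == "welch" and self.welch_segment_s < 2.0 / self.B:
            raise ValueError("welch_segment_s must be >= 2/B to resolve the band")


@dataclass
class ConnectivityMatrix:
    """Symmetric per-subject, per-band connectivity matrix with entries in [0, 1]."""

    region_labels: list[str]
    band: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.region_labels):
            raise ValueError("label count does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains NaN/Inf")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("connectivity entries must lie in [0, 1]")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("connectivity diagonal must be zero")
        self.values = v


def _z_power_spectrum(dphi: np.ndarray, fs: float, cfg: PlmConfig):
    """Power spectral density of exp(i*dphi) over the full (two-sided) axis."""
    z = np.exp(1j * dphi)
    if cfg.spectral_estimator == "periodogram":
        # Plain boxcar periodogram |FFT|^2 / (N*fs), computed directly.
        n = z.size
        f = np.fft.fftfreq(n, d=1.0 / fs)
        p = np.abs(np.fft.fft(z)) ** 2 / (n * fs)
    else:
        nper = min(int(round(cfg.welch_segment_s * fs)), z.size)
        f, p = welch(z, fs=fs, nperseg=nper, return_onesided=False, detrend=False)
    return f, p


def plm_pair(phase_i: np.ndarray, phase_j: np.ndarray, cfg: PlmConfig,
             fs: float) -> float:
    """PLM between two phase time courses (radians), in [0, 1].

    Symmetric in its arguments.  Returns 0 (with a logged warning) when
    the interferometric signal has no spectral power left after DC
    removal, i.e. the phase difference is constant — the degenerate
    instantaneous-mixing case.
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape or phase_i.ndim != 1:
        raise ValueError("phase rows must be 1-D and of equal length")
    if phase_i.size < 10 * fs:
        raise ValueError("need at least 10 s of phase data for a stable PLM")
    # Swapping the inputs conjugates z and mirrors its spectrum; the
    # integration band is symmetric, so the PLM is unchanged.  Canonicalize
    # the sign of the phase difference so both argument orders transform
    # the identical array: plm_pair(x, y) == plm_pair(y, x) bit for bit.
    dphi = phase_i - phase_j
    nz = np.flatnonzero(dphi)
    if nz.size and dphi[nz[0]] < 0:
        dphi = -dphi
    # The periodogram is |S_z(f)|^2 — the spectral energy density of the
    # interferometric signal; the PLM is its in-band fraction.
    f, p = _z_power_spectrum(dphi, fs, cfg)
    p = p.astype(float)
    total_with_dc = p.sum()
    if cfg.discard_dc:
        p[f == 0.0] = 0.0
    total = p.sum()
    if not np.isfinite(total) or total <= 1e-12 * max(total_with_dc, 1e-300):
        logger.warning("degenerate constant phase difference; returning PLM = 0")
        return 0.0
    inband = p[np.abs(f) <= cfg.B].sum()
    return float(inband / total)


def plm_matrix(phases: PhaseSeries, band: str = "",
               cfg: PlmConfig | None = None) -> ConnectivityMatrix:
    """All-pairs PLM matrix for one subject.

    Computed as the plain pairwise loop over :func:`plm_pair` — the matrix
    entries are exactly the pairwise values, the diagonal is zero, and
    symmetry holds by construction.
    """
    cfg = cfg or PlmConfig()
    n = len(phases.region_labels)
    if n < 2:
        raise ValueError("need at least two regions")
    ph = phases.phases
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = plm_pair(ph[i], ph[j], cfg, phases.fs)
            out[i, j] = out[j, i] = v
    return ConnectivityMatrix(list(phases.region_labels), band, out)
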
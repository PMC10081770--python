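"""Log-binned dB power spectra on device, gravity-aligned and PC channels.

Each block (or arbitrary-length window) is mean-removed, Hann-tapered and
Fourier-transformed; one-sided power densities are averaged inside
log-spaced frequency bins and expressed in dB.  Three channel sets are
supported:

* ``device`` — the raw x, y, z axes;
* ``g``     — projections onto a causal gravity-frame estimate (g, dg, ddg);
* ``pc``    — per-frequency principal-oscillation amplitudes (PC1, PC2),
  invariant to fixed rotations of the device coordinate system.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .blocks import Block
from .core import AccelRecording

DB_EPS = 1e-12

DEVICE_CHANNELS = ("x", "y", "z")
G_CHANNELS = ("g", "dg", "ddg")
PC_CHANNELS = ("pc1", "pc2")


@dataclass
class FrequencyBinning:
    """Logarithmically spaced frequency bins."""

    n_bins: int
    f_min: float
    f_max: float
    edges: np.ndarray  # (n_bins + 1,)
    centers: np.ndarray  # geometric means, (n_bins,)


def log_bin_edges(n_bins: int, f_min: float, f_max: float) -> FrequencyBinning:
    """Geometric progression of ``n_bins`` bins from ``f_min`` to ``f_max``."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if not 0 < f_min < f_max:
        raise ValueError("require 0 < f_min < f_max")
    edges = np.geomspace(f_min, f_max, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return FrequencyBinning(n_bins, f_min, f_max, edges, centers)


def default_binning(sampling_rate: float = 50.0) -> FrequencyBinning:
    """Eleven log bins over 0.25 Hz to the 25 Hz Nyquist band."""
    return log_bin_edges(11, 0.25, sampling_rate / 2.0)


@dataclass
class SpectralBlock:
    """Per-block channels x bins dB power matrix."""

    subject_id: str
    start_time: float
    channels: tuple[str, ...]
    power_db: np.ndarray  # (n_channels, n_bins)
    centers: np.ndarray  # bin centre frequencies, Hz


@dataclass
class GravityFrame:
    """Per-sample right-handed orthonormal triad (ghat, dghat, ddghat)."""

    ghat: np.ndarray  # (n, 3)
    dghat: np.ndarray
    ddghat: np.ndarray


# ---------------------------------------------------------------------------
# spectral primitives
# ---------------------------------------------------------------------------


def _tapered_rfft(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, float]:
    """rfft of mean-removed, Hann-tapered columns; returns (freqs, X, scale).

    ``scale`` converts |X|^2 to a one-sided power spectral density.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    win = sps.windows.hann(n, sym=False)
    xt = (x - x.mean(axis=0)) * win[:, None]
    X = np.fft.rfft(xt, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 2.0 / (fs * np.sum(win**2))
    return freqs, X, scale


def _bin_indices(freqs: np.ndarray, binning: FrequencyBinning) -> list[np.ndarray]:
    """FFT-frequency index sets per bin (last bin inclusive of f_max)."""
    sets = []
    for j in range(binning.n_bins):
        lo, hi = binning.edges[j], binning.edges[j + 1]
        if j == binning.n_bins - 1:
            mask = (freqs >= lo) & (freqs <= hi * (1 + 1e-12))
        else:
            mask = (freqs >= lo) & (freqs < hi)
        sets.append(np.nonzero(mask)[0])
    return sets


def _bin_power(power: np.ndarray, freqs: np.ndarray,
               binning: FrequencyBinning) -> np.ndarray:
    """Mean power density per bin; empty bins get zero power (dB floor)."""
    out = np.zeros((power.shape[1], binning.n_bins))
    for j, idx in enumerate(_bin_indices(freqs, binning)):
        if idx.size:
            out[:, j] = power[idx].mean(axis=0)
    return out


def spectrum_db(x: np.ndarray, fs: float,
                binning: FrequencyBinning) -> np.ndarray:
    """Log-binned dB power spectrum of each column of ``x``.

    Returns a (n_channels, n_bins) array of 10*log10(power + eps) values.
    """
    freqs, X, scale = _tapered_rfft(x, fs)
    power = scale * np.abs(X) ** 2
    binned = _bin_power(power, freqs, binning)
    return 10.0 * np.log10(binned + DB_EPS)


# ---------------------------------------------------------------------------
# gravity frame
# ---------------------------------------------------------------------------


def estimate_gravity_frame(samples: np.ndarray, rate: float,
                           cutoff: float = 0.1) -> GravityFrame:
    """Per-sample gravity triad from a causal 0.1 Hz low-pass estimate.

    ghat is the normalised first-order exponentially smoothed signal; dghat
    is the component of its first difference orthogonal to ghat; ddghat
    completes a right-handed triad by cross product.  Samples where the
    gravity direction is momentarily constant fall back to a deterministic
    completion (the least-aligned device axis, orthogonalised).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3 or samples.shape[0] < 2:
        raise ValueError("need an (n >= 2, 3) sample array")
    alpha = 1.0 - np.exp(-2.0 * np.pi * cutoff / rate)
    # y[k] = alpha x[k] + (1 - alpha) y[k-1], initialised at x[0]
    zi = (1.0 - alpha) * samples[0]
    g, _ = sps.lfilter([alpha], [1.0, alpha - 1.0], samples, axis=0, zi=zi[None, :])
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("gravity estimate vanished; cannot build a frame")
    ghat = g / norms

    d = np.diff(ghat, axis=0, prepend=ghat[:1])
    if d.shape[0] > 1:
        d[0] = d[1]  # first difference undefined at the first sample
    d_perp = d - (np.sum(d * ghat, axis=1, keepdims=True)) * ghat
    dnorm = np.linalg.norm(d_perp, axis=1)
    degenerate = dnorm < 1e-9
    if np.any(degenerate):
        idx = np.argmin(np.abs(ghat[degenerate]), axis=1)
        fallback = np.eye(3)[idx]
        fb_perp = fallback - np.sum(fallback * ghat[degenerate], axis=1,
                                    keepdims=True) * ghat[degenerate]
        d_perp[degenerate] = fb_perp
        dnorm = np.linalg.norm(d_perp, axis=1)
    dghat = d_perp / dnorm[:, None]
    ddghat = np.cross(ghat, dghat)
    return GravityFrame(ghat, dghat, ddghat)


def project_g_channels(samples: np.ndarray, frame: GravityFrame) -> np.ndarray:
    """Project raw accelerations onto the gravity triad -> (n, 3) g/dg/ddg."""
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] != frame.ghat.shape[0]:
        raise ValueError("frame length does not match samples")
    return np.stack([
        np.sum(samples * frame.ghat, axis=1),
        np.sum(samples * frame.dghat, axis=1),
        np.sum(samples * frame.ddghat, axis=1),
    ], axis=1)


# ---------------------------------------------------------------------------
# principal-oscillation (PC) channels
# ---------------------------------------------------------------------------


def pc_amplitudes(fft_triplet: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-oscillation amplitudes of per-frequency complex 3-vectors.

    For each frequency, the complex Fourier coefficients (c_x, c_y, c_z)
    describe an ellipse in 3-space; the two singular values of the real
    3x2 matrix [Re c, Im c] are the semi-axes of that ellipse.  They are
    invariant to fixed rotations of the device coordinate system.

    Accepts shape (..., 3) complex; returns (pc1, pc2) with pc1 >= pc2.
    """
    c = np.asarray(fft_triplet, dtype=complex)
    if c.shape[-1] != 3:
        raise ValueError("last axis must have length 3")
    m = np.stack([c.real, c.imag], axis=-1)  # (..., 3, 2)
    s = np.linalg.svd(m, compute_uv=False)  # (..., 2) descending
    return s[..., 0], s[..., 1]


def pc_amplitude_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency (pc1, pc2) amplitudes of a tri-axial signal.

    Returns ``(freqs, amps)`` with ``amps`` of shape (n_freqs, 2).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("need an (n, 3) tri-axial signal")
    freqs, X, _ = _tapered_rfft(x, fs)
    pc1, pc2 = pc_amplitudes(X)
    return freqs, np.stack([pc1, pc2], axis=1)


def pc_spectrum_db(x: np.ndarray, fs: float,
                   binning: FrequencyBinning) -> np.ndarray:
    """Log-binned dB spectrum of the two PC channels, (2, n_bins)."""
    x = np.asarray(x, dtype=float)
    freqs, X, scale = _tapered_rfft(x, fs)
    pc1, pc2 = pc_amplitudes(X)
    power = scale * np.stack([pc1, pc2], axis=1) ** 2
    binned = _bin_power(power, freqs, binning)
    return 10.0 * np.log10(binned + DB_EPS)


# ---------------------------------------------------------------------------
# per-block feature extraction
# ---------------------------------------------------------------------------


def channel_signals(xyz: np.ndarray, fs: float,
                    channel_sets: Sequence[str] = ("device", "g")) -> dict[str, np.ndarray]:
    """Named 1-D channel signals for the requested time-domain sets."""
    out: dict[str, np.ndarray] = {}
    for cs in channel_sets:
        if cs == "device":
            for k, name in enumerate(DEVICE_CHANNELS):
                out[name] = xyz[:, k]
        elif cs == "g":
            frame = estimate_gravity_frame(xyz, fs)
            proj = project_g_channels(xyz, frame)
            for k, name in enumerate(G_CHANNELS):
                out[name] = proj[:, k]
        else:
            raise ValueError(f"unknown time-domain channel set {cs!r}")
    return out


def spectral_block(block: Block, binning: FrequencyBinning,
                   channel_set: str = "device") -> SpectralBlock:
    """Spectral features of one accepted block on the requested channel set."""
    if not block.valid:
        raise ValueError("refusing to featurise an invalid block")
    xyz = block.data.T
    fs = block.sampling_rate
    if channel_set == "pc":
        power_db = pc_spectrum_db(xyz, fs, binning)
        channels = PC_CHANNELS
    elif channel_set in ("device", "g"):
        sigs = channel_signals(xyz, fs, (channel_set,))
        names = DEVICE_CHANNELS if channel_set == "device" else G_CHANNELS
        stacked = np.stack([sigs[n] for n in names], axis=1)
        power_db = spectrum_db(stacked, fs, binning)
        channels = names
    else:
        raise ValueError(f"unknown channel set {channel_set!r}")
    return SpectralBlock(block.subject_id, block.start_time, tuple(channels),
                         power_db, binning.centers)


def spectral_feature_table(recordings: Sequence[AccelRecording],
                           binning: FrequencyBinning | None = None,
                           channel_sets: Sequence[str] = ("device", "g"),
                           gap_tol: float = 1.0,
                           drift_tol: float = 0.01) -> pd.DataFrame:
    """Tidy feature table: one row per (subject, block, channel).

    Blocks failing timestamp validation are excluded.  Columns: subject,
    cohort, start_time, channel and ``bin0`` .. ``bin{n-1}``.
    """
    from .blocks import segment_blocks, validate_block

    rows = []
    for rec in recordings:
        bn = binning or default_binning(rec.sampling_rate)
        for blk in segment_blocks(rec):
            blk = validate_block(blk, gap_tol=gap_tol, drift_tol=drift_tol)
            if not blk.valid:
                continue
            for cs in channel_sets:
                sb = spectral_block(blk, bn, cs)
                for ci, ch in enumerate(sb.channels):
                    row = {"subject": rec.subject_id, "cohort": rec.cohort,
                           "start_time": blk.start_time, "channel": ch}
                    row.update({f"bin{j}": sb.power_db[ci, j] for j in range(bn.n_bins)})
                    rows.append(row)
    return pd.DataFrame(rows)


def bin_columns(df: pd.DataFrame) -> list[str]:
    """The ordered bin feature columns of a tidy spectral table."""
    cols = [c for c in df.columns if c.startswith("bin")]
    return sorted(cols, key=lambda c: int(c[3:]))
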
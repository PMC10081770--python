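"""Event-aligned symptom characterisation with a rank-1 factorial model.

Diary events (tremor vs other movement symptoms, reported durations above
two hours rejected) are centred on their midpoints; the spectral blocks
nearest to a grid of block-hop offsets around each midpoint are stacked
into an events x time x frequency x channel tensor of dB log-amplitudes.
The shared symptom signature is then the rank-1 factorial model

    L_itfc ~ N(u_t * v_f * w_c + b, sigma^2)

whose maximum-likelihood fit (least squares, alternating over u, v, w, b)
yields a temporal envelope u, a spectral envelope v, and a channel
envelope w, identified up to scale by the unit-norm gauge on v and w.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DiaryEvent
from .spectra import SpectralBlock

log = logging.getLogger(__name__)


def select_events(diary: Sequence[DiaryEvent],
                  max_duration_hours: float = 2.0) -> list[DiaryEvent]:
    """Drop events whose reported duration exceeds the rejection cap.

    Reported durations longer than the cap (default two hours) are too
    unreliable to centre an analysis on; surviving events are anchored at
    their midpoint timestamps.
    """
    cap_min = max_duration_hours * 60.0
    return [e for e in diary if e.duration_minutes <= cap_min]


@dataclass
class EventTensor:
    """events x offsets x bins x channels tensor of dB log-amplitudes."""

    L: np.ma.MaskedArray  # (I, T, F, C)
    offsets: np.ndarray  # block-hop units, symmetric around 0
    events: list[DiaryEvent]
    bins: np.ndarray  # bin centre frequencies
    channels: tuple[str, ...]


def build_event_tensor(events: Sequence[DiaryEvent],
                       spectral_blocks: Sequence[SpectralBlock],
                       K: int = 5,
                       hop_seconds: float | None = None) -> EventTensor:
    """Stack the blocks nearest to midpoint + k*hop for k = -K..K.

    A cell is masked (never zero-filled) when the subject has no block
    whose centre lies within half a hop of the target time; events with
    all offsets missing are dropped and logged.  Blocks are matched on
    their centres (start + half a block) so that offset 0 is the block
    centred on the reported symptom midpoint.
    """
    if not spectral_blocks:
        raise ValueError("no spectral blocks supplied")
    first = spectral_blocks[0]
    channels = first.channels
    bins = first.centers
    for sb in spectral_blocks:
        if sb.channels != channels or sb.power_db.shape != first.power_db.shape:
            raise ValueError("spectral blocks must share one binning and channel set")
    if hop_seconds is None:
        from .blocks import HOP
        hop_seconds = HOP / 50.0

    by_subject: dict[str, list[SpectralBlock]] = {}
    for sb in spectral_blocks:
        by_subject.setdefault(sb.subject_id, []).append(sb)
    # block centre = start + one hop (a block spans two hops)
    centers_of = {s: np.array([b.start_time for b in lst]) + hop_seconds
                  for s, lst in by_subject.items()}

    offsets = np.arange(-K, K + 1)
    T = offsets.size
    F, C = bins.size, len(channels)
    slabs, kept = [], []
    for ev in events:
        if ev.subject_id not in by_subject:
            log.warning("event for %s has no spectra; dropped", ev.subject_id)
            continue
        st = centers_of[ev.subject_id]
        lst = by_subject[ev.subject_id]
        slab = np.ma.masked_all((T, F, C))
        for ti, k in enumerate(offsets):
            target = ev.midpoint + k * hop_seconds
            j = int(np.argmin(np.abs(st - target)))
            if abs(st[j] - target) <= hop_seconds / 2:
                slab[ti] = lst[j].power_db.T  # (F, C)
        if slab.mask.all():
            log.warning("event at t=%.0f for %s has no covered offsets; dropped",
                        ev.midpoint, ev.subject_id)
            continue
        slabs.append(slab)
        kept.append(ev)
    if not slabs:
        raise ValueError("no events with spectral coverage")
    L = np.ma.stack(slabs)
    return EventTensor(L, offsets, kept, bins, channels)


@dataclass
class EnvelopeFit:
    """Rank-1 factorial fit: temporal, spectral and channel envelopes."""

    u: np.ndarray  # (T,) temporal envelope, carries the scale
    v: np.ndarray  # (F,) spectral envelope, unit norm
    w: np.ndarray  # (C,) channel envelope, unit norm
    b: float  # intercept, dB
    sigma2: float  # residual variance
    converged: bool
    n_iter: int
    degenerate: bool = False
    objective_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self) -> np.ndarray:
        """Model surface u x v x w + b, shape (T, F, C)."""
        return np.einsum("t,f,c->tfc", self.u, self.v, self.w) + self.b


def _as_masked(L) -> np.ma.MaskedArray:
    if isinstance(L, EventTensor):
        L = L.L
    if not np.ma.isMaskedArray(L):
        L = np.ma.asarray(np.asarray(L, dtype=float))
    if L.ndim != 4:
        raise ValueError("tensor must be events x offsets x bins x channels")
    return L


def fit_rank1_envelope(tensor, tol: float = 1e-8,
                       max_iter: int = 1000) -> EnvelopeFit:
    """Least-squares fit of L_itfc = u_t v_f w_c + b on observed cells.

    Alternating exact coordinate minimisation over u, v, w and b; the
    event index is marginalised (envelopes are shared across events).
    Initialisation takes b as the grand mean and (u, v, w) from the
    leading singular vectors of the event-averaged tensor's unfoldings.
    The objective is non-increasing by construction and asserted so.
    """
    Lm = _as_masked(tensor)
    I, T, F, C = Lm.shape
    if min(T, F, C) < 2:
        raise ValueError("need at least 2 levels along each of t, f, c")
    M = (~np.ma.getmaskarray(Lm)).astype(float)
    n_obs = M.sum()
    if n_obs == 0:
        raise ValueError("tensor is fully masked")
    L = Lm.filled(0.0)

    b = float((L * M).sum() / n_obs)
    # init from the event-averaged centred tensor
    cnt = np.maximum(M.sum(axis=0), 1.0)
    abar = ((L - b) * M).sum(axis=0) / cnt  # (T, F, C)
    u = np.linalg.svd(abar.reshape(T, -1), compute_uv=True)[0][:, 0]
    v = np.linalg.svd(abar.transpose(1, 0, 2).reshape(F, -1), compute_uv=True)[0][:, 0]
    w = np.linalg.svd(abar.transpose(2, 0, 1).reshape(C, -1), compute_uv=True)[0][:, 0]

    def objective() -> float:
        pred = np.einsum("t,f,c->tfc", u, v, w) + b
        return float((((L - pred) ** 2) * M).sum())

    prev = objective()
    trace = [prev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        D = (L - b) * M
        num = np.einsum("itfc,f,c->t", D, v, w)
        den = np.einsum("itfc,f,c->t", M, v**2, w**2)
        u = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

        D = (L - b) * M
        num = np.einsum("itfc,t,c->f", D, u, w)
        den = np.einsum("itfc,t,c->f", M, u**2, w**2)
        v = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

        num = np.einsum("itfc,t,f->c", D, u, v)
        den = np.einsum("itfc,t,f->c", M, u**2, v**2)
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

        fit_part = np.einsum("t,f,c->tfc", u, v, w)
        b = float(((L - fit_part) * M).sum() / n_obs)

        obj = objective()
        assert obj <= prev + 1e-9 * max(1.0, prev), "ALS objective increased"
        trace.append(obj)
        if abs(prev - obj) <= tol * max(prev, 1e-12):
            converged = True
            prev = obj
            break
        prev = obj

    sigma2 = prev / n_obs
    nv, nw = float(np.linalg.norm(v)), float(np.linalg.norm(w))
    if nv < 1e-12 or nw < 1e-12:
        # constant tensor: no factorial structure
        return EnvelopeFit(np.zeros(T), np.full(F, 1 / np.sqrt(F)),
                           np.full(C, 1 / np.sqrt(C)), b, sigma2,
                           converged, it, degenerate=True,
                           objective_trace=np.asarray(trace))
    u = u * nv * nw
    v, w = v / nv, w / nw
    sv = np.sign(v[np.argmax(np.abs(v))]) or 1.0
    sw = np.sign(w[np.argmax(np.abs(w))]) or 1.0
    v, w = v * sv, w * sw
    u = u * sv * sw
    return EnvelopeFit(u, v, w, b, sigma2, converged, it,
                       objective_trace=np.asarray(trace))


def envelope_summary(fit: EnvelopeFit, tensor: EventTensor) -> dict:
    """JSON-ready description of one envelope fit."""
    return {
        "u": fit.u.tolist(),
        "v": fit.v.tolist(),
        "w": fit.w.tolist(),
        "b": fit.b,
        "sigma2": fit.sigma2,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "degenerate": fit.degenerate,
        "offsets": tensor.offsets.tolist(),
        "bin_centers_hz": tensor.bins.tolist(),
        "channels": list(tensor.channels),
        "n_events": len(tensor.events),
    }
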
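"""Recover per-pixel SPAD noise parameters from dark-frame stacks.

In a dark acquisition the only event sources are dark counts, afterpulsing
and crosstalk, so the three parameter maps can be separated by classifying
each detection event from its spatio-temporal signature:

* two consecutive detections at the same pixel -> **afterpulse** event;
* a detection with a simultaneously firing neighbour -> **crosstalk** event,
  *unless* it already qualified as an afterpulse (afterpulsing is typically
  1-2 orders of magnitude more probable than crosstalk, so ambiguous events
  are assigned to the afterpulse class — the priority rule that makes the
  two classes disjoint);
* everything else is a residual (dark-count) event.

The per-pixel estimators are event-count ratios:

    p_ap(x,y)  = sum_n I_ap  / sum_n (I_dark - I_ap - I_ct)
    p_ct(x,y)  = sum_n I_ct  / sum_n (I_dark - I_ap - I_ct)
    N_dcr(x,y) = sum_n (I_dark - I_ap - I_ct) / n_total

with 0/0 defined as 0 (a pixel that never fires cleanly gives no evidence of
either noise source). Estimates are raw ratios; an optional debiasing flag
subtracts the analytic chance-coincidence rate (two independent dark counts
in consecutive frames mimic an afterpulse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .noise_model import BinaryFrameStack, SensorCalibration, neighbor_shifts, shift2d

__all__ = [
    "EventMaps",
    "classify_events",
    "estimate_afterpulse_map",
    "estimate_crosstalk_map",
    "estimate_dcr_map",
    "calibrate_from_dark",
]


@dataclass(frozen=True)
class EventMaps:
    """Per-frame classification of dark-stack detections.

    ``i_ap`` and ``i_ct`` are {0,1} arrays aligned with the input stack;
    a 1 marks a detection classified as afterpulse / crosstalk. The priority
    rule guarantees ``i_ap & i_ct == 0`` everywhere.
    """

    i_ap: np.ndarray
    i_ct: np.ndarray
    connectivity: int = 4

    @property
    def n_afterpulse(self) -> np.ndarray:
        return self.i_ap.sum(axis=0, dtype=np.int64)

    @property
    def n_crosstalk(self) -> np.ndarray:
        return self.i_ct.sum(axis=0, dtype=np.int64)


def classify_events(stack: BinaryFrameStack, connectivity: int = 4) -> EventMaps:
    """Classify every detection in a dark stack as afterpulse, crosstalk or residual.

    ``i_ap(x,y,n) = 1`` iff the pixel fired in frames ``n-1`` and ``n``
    (n >= 1). ``i_ct(x,y,n) = 1`` iff the pixel fired, at least one
    neighbour fired in the same frame, and the event was *not* classified as
    an afterpulse.

    The stack is assumed to be a dark acquisition; that contract cannot be
    verified from the data.
    """
    if stack.n_frames < 2:
        raise ValueError("event classification needs at least 2 frames "
                         "(afterpulsing is defined against the previous frame)")
    frames = stack.frames.astype(bool)
    i_ap = np.zeros_like(frames)
    i_ap[1:] = frames[1:] & frames[:-1]

    neighbour_any = np.zeros_like(frames)
    for dy, dx in neighbor_shifts(connectivity):
        # shift every frame at once: pad/crop along the two spatial axes
        shifted = np.zeros_like(frames)
        h, w = frames.shape[1:]
        ys = slice(max(dy, 0), h + min(dy, 0))
        xs = slice(max(dx, 0), w + min(dx, 0))
        ys_src = slice(max(-dy, 0), h + min(-dy, 0))
        xs_src = slice(max(-dx, 0), w + min(-dx, 0))
        shifted[:, ys, xs] = frames[:, ys_src, xs_src]
        neighbour_any |= shifted
    i_ct = frames & neighbour_any & ~i_ap
    return EventMaps(
        i_ap=i_ap.astype(np.uint8), i_ct=i_ct.astype(np.uint8),
        connectivity=connectivity,
    )


def _check_alignment(stack: BinaryFrameStack, events: EventMaps) -> None:
    if events.i_ap.shape != stack.frames.shape:
        raise ValueError(
            f"event maps shape {events.i_ap.shape} does not match "
            f"stack shape {stack.frames.shape}"
        )


def _residual_counts(stack: BinaryFrameStack, events: EventMaps) -> np.ndarray:
    """Per-pixel count of detections classified as neither afterpulse nor crosstalk."""
    total = stack.frames.sum(axis=0, dtype=np.int64)
    return total - events.n_afterpulse - events.n_crosstalk


def _ratio_map(numer: np.ndarray, denom: np.ndarray, name: str) -> np.ndarray:
    out = np.zeros(numer.shape, dtype=np.float64)
    np.divide(numer, denom, out=out, where=denom > 0)
    if np.any(out > 1.0):
        warnings.warn(
            f"{name} estimate exceeded 1 at {int((out > 1).sum())} pixel(s); "
            "clipping to [0, 1]", stacklevel=3,
        )
        out = np.clip(out, 0.0, 1.0)
    return out


def estimate_afterpulse_map(stack: BinaryFrameStack, events: EventMaps) -> np.ndarray:
    """Per-pixel afterpulse probability: afterpulse events over clean events."""
    _check_alignment(stack, events)
    return _ratio_map(events.n_afterpulse.astype(np.float64),
                      _residual_counts(stack, events).astype(np.float64), "p_ap")


def estimate_crosstalk_map(stack: BinaryFrameStack, events: EventMaps) -> np.ndarray:
    """Per-pixel crosstalk probability: crosstalk events over clean events."""
    _check_alignment(stack, events)
    return _ratio_map(events.n_crosstalk.astype(np.float64),
                      _residual_counts(stack, events).astype(np.float64), "p_ct")


def estimate_dcr_map(
    stack: BinaryFrameStack, events: EventMaps, n_total: int
) -> np.ndarray:
    """Per-pixel dark-count event rate: residual detections per frame."""
    _check_alignment(stack, events)
    if n_total != stack.n_frames:
        raise ValueError(
            f"n_total ({n_total}) must equal the stack's frame count "
            f"({stack.n_frames})"
        )
    return _residual_counts(stack, events) / float(n_total)


def _neighbor_sum(a: np.ndarray, connectivity: int) -> np.ndarray:
    out = np.zeros_like(a)
    for dy, dx in neighbor_shifts(connectivity):
        out += shift2d(a, dy, dx)
    return out


def invert_event_rates(
    fire_rate: np.ndarray,
    ap_rate: np.ndarray,
    ct_rate: np.ndarray,
    connectivity: int = 4,
    n_iter: int = 40,
    damping: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic bias correction: invert expected classifier event rates.

    The raw ratio estimators are biased because the classifier also fires on
    chance coincidences and counts a crosstalk pair at *both* pixels. To
    first order in the (small) per-frame rates, the stationary expectations
    of the observed per-pixel rates — ``f`` (any fire), ``A``
    (afterpulse-classified), ``C`` (crosstalk-classified) — given the true
    parameters ``d`` (dark event probability), ``a`` (afterpulse
    probability) and ``c`` (crosstalk probability) are::

        f_i = d_i + f_i a_i + c_i S_i              S_i = sum of neighbours' s
        A_i = f_i a_i + f_i^2 (1 - a_i)^2          (true ap + chance repeat)
        C_i = (1 - A_i/f_i) * (f_i F_i + c_i S_i + s_i C'_i)

    with ``s_i = f_i - c_i S_i`` the seed (non-crosstalk) rate, ``F_i`` the
    neighbour sum of ``f`` (chance adjacency), ``c_i S_i`` the received and
    ``s_i C'_i`` the emitted half of each true crosstalk pair, and the
    leading factor removing events claimed by the afterpulse priority rule.
    Solving this small fixed-point system per pixel recovers (d, a, c);
    pixels that never fire return zeros. The emitted-pair term couples each
    pixel to its neighbours with unit gain, so the iteration is damped
    (relaxation factor ``damping``) to converge instead of oscillating.

    Returns ``(dark_rate, p_ap, p_ct)``.
    """
    f = np.asarray(fire_rate, dtype=np.float64)
    A = np.asarray(ap_rate, dtype=np.float64)
    C = np.asarray(ct_rate, dtype=np.float64)
    pos = f > 0
    a_over_f = np.divide(A, f, out=np.zeros_like(f), where=pos)
    c_corr = np.divide(C, 1.0 - a_over_f,
                       out=np.zeros_like(f), where=(1.0 - a_over_f) > 0)

    a = a_over_f.copy()
    c = np.zeros_like(f)
    s = f.copy()
    Fn = _neighbor_sum(f, connectivity)
    for _ in range(n_iter):
        S = _neighbor_sum(s, connectivity)
        Cn = _neighbor_sum(c, connectivity)
        numer = c_corr - f * Fn - s * Cn
        c_new = np.clip(np.divide(numer, S, out=np.zeros_like(f), where=S > 0),
                        0.0, 1.0)
        c += damping * (c_new - c)
        a = np.clip(a_over_f - f * (1.0 - a) ** 2, 0.0, 1.0)
        s = np.clip(f - c * S, 0.0, 1.0)
    d = np.clip(s - f * a, 0.0, 1.0)
    return d, a, c


def calibrate_from_dark(
    stack: BinaryFrameStack,
    pde: np.ndarray | float = 1.0,
    connectivity: int = 4,
    debias: bool = True,
) -> SensorCalibration:
    """Full calibration workflow: classify a dark stack, estimate all maps.

    With ``debias=True`` (default) the raw classifier event rates are passed
    through :func:`invert_event_rates`, which removes the analytic
    chance-coincidence and pair-double-counting biases; with
    ``debias=False`` the maps are the raw event-count ratios (the two agree
    as the dark rate tends to zero, but the raw crosstalk ratio is dominated
    by chance adjacencies whenever ``p_ct`` is below the per-frame firing
    rate).

    The DCR map is stored as a Poisson expectation per frame
    (``lambda = -log(1 - rate)``, inverting the 1-bit Bernoulli conversion)
    so the returned calibration is directly consumable by the simulator; at
    realistic dark rates (<~1e-2) rate and expectation differ by <0.5%.

    PDE cannot be observed in darkness; it is taken from configuration
    (e.g. a manufacturer map) and defaults to all-ones.
    """
    events = classify_events(stack, connectivity=connectivity)
    if debias:
        n = float(stack.n_frames)
        fire = stack.frames.mean(axis=0)
        rate, p_ap, p_ct = invert_event_rates(
            fire, events.n_afterpulse / n, events.n_crosstalk / n,
            connectivity=connectivity,
        )
    else:
        p_ap = estimate_afterpulse_map(stack, events)
        p_ct = estimate_crosstalk_map(stack, events)
        rate = estimate_dcr_map(stack, events, stack.n_frames)
    # invert the per-frame Bernoulli conversion; rate == 1 would be a hot pixel
    lam = -np.log1p(-np.clip(rate, 0.0, 1.0 - 1e-12))
    return SensorCalibration(
        pde=pde, dcr=lam, p_ap=p_ap, p_ct=p_ct,
        shape=stack.sensor_shape, connectivity=connectivity,
    )
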
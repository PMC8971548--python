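"""Automatic QRS bounding-box annotation via scale-1 wavelet modulus extrema.

A QRS complex is a sharp transient: its up- and down-strokes are
singularities that show up as modulus extremum pairs of the fine-scale
wavelet detail, with the zero-crossing between a pair sitting at the wave
peak/trough itself.  Using the officially annotated R peak as reference,
the Q trough is found from the modulus extremum of the detail in a window
before R (the Q→R upstroke) and the S trough from the extremum after R
(the R→S downstroke); each extremum is then refined to the adjacent
zero-crossing of the detail, which marks the trough where the smoothed
derivative vanishes.  The QRS bounding rectangle uses Q as the left edge,
S as the right edge, the R amplitude as the top and the smaller of the
Q/S amplitudes as the bottom.

The detail sequence is the undecimated scale-1 output of the
Mallat–Zhong quadratic-spline filter bank, whose scale-1 wavelet filter
is the two-tap derivative kernel (±2); the sign convention here makes an
upstroke a negative detail excursion, so Q is at a modulus *minimum*
before R and S at a modulus *maximum* after R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import Beat, EcgRecord

__all__ = [
    "AnnotateConfig",
    "Fiducials",
    "SignalBox",
    "DegenerateBoxError",
    "BoundaryError",
    "wavelet_detail_j1",
    "locate_qs",
    "beat_box",
    "annotate_record",
]

log = logging.getLogger(__name__)


class DegenerateBoxError(ValueError):
    """R amplitude does not exceed both Q and S amplitudes."""


class BoundaryError(IndexError):
    """Search window extends past the record boundary."""


@dataclass(frozen=True)
class Fiducials:
    """Q/R/S sample indices of one beat (0-based, strictly increasing)."""

    q_sample: int
    r_sample: int
    s_sample: int

    def __post_init__(self) -> None:
        if not self.q_sample < self.r_sample < self.s_sample:
            raise ValueError(
                f"fiducials must satisfy q < r < s, got "
                f"({self.q_sample}, {self.r_sample}, {self.s_sample})"
            )


@dataclass(frozen=True)
class SignalBox:
    """QRS rectangle in the signal frame: samples on x, mV on y."""

    left: int  # q_sample
    right: int  # s_sample
    top: float  # amplitude at R (mV)
    bottom: float  # min(amplitude at Q, amplitude at S) (mV)
    class12: str | None = None

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError("box must satisfy left < right")
        if not self.top > self.bottom:
            raise DegenerateBoxError("box must satisfy top > bottom")


@dataclass(frozen=True)
class AnnotateConfig:
    """Search-window widths, delay compensation and refinement switches.

    search_before_s / search_after_s: extremum search range around R.
    delay_comp_samples: fixed shift applied to located fiducials,
        compensating the group delay of the scale-1 filter (the two-tap
        kernel is half-sample centred, so 0 is appropriate after
        zero-crossing refinement).
    refine_zero_crossing: snap each modulus extremum to the adjacent
        detail zero-crossing (the trough); disable to use the raw
        extremum position.
    allow_inverted: for beats whose R amplitude is a local minimum,
        search with flipped extremum signs instead of failing.
    """

    search_before_s: float = 0.1
    search_after_s: float = 0.1
    delay_comp_samples: int = 0
    refine_zero_crossing: bool = True
    allow_inverted: bool = False


def wavelet_detail_j1(x: np.ndarray) -> np.ndarray:
    """Undecimated scale-1 quadratic-spline wavelet detail of ``x``.

    Same length as the input.  ``d[n] = 2*(x[n] - x[n+1])``: a rising
    edge gives a negative excursion, a falling edge a positive one, and
    the zero-crossing between an extremum pair sits at the local
    extremum of the signal.  A linear ramp maps to a constant (the
    kernel has one vanishing moment, so the *variation* of a ramp
    vanishes and pure offsets map to zero).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("signal too short for scale-1 detail")
    d = np.zeros_like(x)
    d[:-1] = 2.0 * (x[:-1] - x[1:])
    return d


def _zero_cross_left(d: np.ndarray, start: int, limit: int) -> int | None:
    """First index t in (limit, start] with d[t-1] >= 0 > d[t] scanning left."""
    for i in range(start - 1, limit - 1, -1):
        if d[i] >= 0 > d[i + 1]:
            return i + 1
    return None


def _zero_cross_right(d: np.ndarray, start: int, limit: int) -> int | None:
    """First index t in [start, limit) with d[t-1] > 0 >= d[t] scanning right."""
    for i in range(start, limit):
        if d[i - 1] > 0 >= d[i]:
            return i
    return None


def locate_qs(
    detail: np.ndarray,
    signal: np.ndarray,
    r_sample: int,
    fs: float,
    cfg: AnnotateConfig = AnnotateConfig(),
) -> Fiducials:
    """Locate Q and S around a reference R peak from the scale-1 detail.

    Q: modulus minimum of the detail in the window before R (the Q→R
    upstroke), refined to the preceding zero-crossing (the Q trough).
    S: modulus maximum after R (the R→S downstroke), refined to the
    following zero-crossing (the S trough).  Raises
    :class:`BoundaryError` when either window leaves the record.
    """
    detail = np.asarray(detail, dtype=float)
    signal = np.asarray(signal, dtype=float)
    wb = max(2, int(round(cfg.search_before_s * fs)))
    wa = max(2, int(round(cfg.search_after_s * fs)))
    lo, hi = r_sample - wb, r_sample + wa
    if lo < 0 or hi >= signal.size:
        raise BoundaryError(
            f"search window [{lo}, {hi}] outside record of "
            f"{signal.size} samples for R at {r_sample}"
        )

    d = detail
    if cfg.allow_inverted:
        # inverted QRS: R annotated on a local minimum of the signal
        seg = signal[lo : hi + 1]
        if signal[r_sample] <= np.median(seg):
            d = -detail

    before = d[lo:r_sample]
    after = d[r_sample + 1 : hi + 1]
    # ties broken toward R: take the last argmin / first argmax
    m_q = lo + (before.size - 1 - int(np.argmin(before[::-1])))
    m_s = r_sample + 1 + int(np.argmax(after))

    q, s = m_q, m_s
    if cfg.refine_zero_crossing:
        zq = _zero_cross_left(d, m_q, lo)
        zs = _zero_cross_right(d, m_s, hi + 1)
        if zq is not None:
            q = zq
        if zs is not None:
            s = zs

    q -= cfg.delay_comp_samples
    s -= cfg.delay_comp_samples
    q = min(max(q, lo), r_sample - 1)
    s = max(min(s, hi), r_sample + 1)
    return Fiducials(q, r_sample, s)


def beat_box(
    signal: np.ndarray, fid: Fiducials, class12: str | None = None
) -> SignalBox:
    """QRS rectangle: [q, s] on the sample axis, [min(Q,S) amp, R amp] on mV.

    Raises :class:`DegenerateBoxError` when the R amplitude does not top
    both the Q and S amplitudes (e.g. an inverted QRS complex).
    """
    signal = np.asarray(signal, dtype=float)
    top = float(signal[fid.r_sample])
    bottom = float(min(signal[fid.q_sample], signal[fid.s_sample]))
    return SignalBox(fid.q_sample, fid.s_sample, top, bottom, class12)


def annotate_record(
    record: EcgRecord,
    beats: list[Beat],
    cfg: AnnotateConfig = AnnotateConfig(),
    lead: str | None = None,
) -> tuple[list[SignalBox], list[Fiducials]]:
    """Annotate every usable beat of a (preprocessed) record.

    Search windows are clipped at the midpoint toward neighbouring R
    peaks so boxes of consecutive beats can never overlap on the sample
    axis.  Beats whose windows leave the record, or whose box is
    degenerate, are skipped with a log message.
    """
    x = record.lead(lead) if lead else record.signal[:, 0]
    detail = wavelet_detail_j1(x)
    boxes: list[SignalBox] = []
    fids: list[Fiducials] = []
    n_skipped = 0
    for i, beat in enumerate(beats):
        beat_cfg = cfg
        # clip windows to half the RR interval toward each neighbour
        wb, wa = cfg.search_before_s, cfg.search_after_s
        if i > 0:
            wb = min(wb, (beat.r_sample - beats[i - 1].r_sample) / (2 * record.fs))
        if i + 1 < len(beats):
            wa = min(wa, (beats[i + 1].r_sample - beat.r_sample) / (2 * record.fs))
        if (wb, wa) != (cfg.search_before_s, cfg.search_after_s):
            beat_cfg = AnnotateConfig(
                wb, wa, cfg.delay_comp_samples,
                cfg.refine_zero_crossing, cfg.allow_inverted,
            )
        try:
            fid = locate_qs(detail, x, beat.r_sample, record.fs, beat_cfg)
            box = beat_box(x, fid, beat.class12)
        except (BoundaryError, DegenerateBoxError) as exc:
            n_skipped += 1
            log.warning(
                "record %s: skipping beat at sample %d: %s",
                record.record_id, beat.r_sample, exc,
            )
            continue
        boxes.append(box)
        fids.append(fid)
    if n_skipped:
        log.info(
            "record %s: annotated %d beats, skipped %d",
            record.record_id, len(boxes), n_skipped,
        )
    return boxes, fids
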
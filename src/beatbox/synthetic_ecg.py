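"""Synthetic ECG records with exact ground-truth fiducials.

Each beat is a sum of Gaussian bumps for the P, Q, R, S and T waves.
Gaussian morphology is the simplest shape with unambiguous analytic
fiducials — the Q/R/S truth is the arg-extremum of the rendered trace
near each component centre — which is all the downstream annotation
algorithm needs (sharp Q/R/S transients).  The 12 beat classes are
expressed as morphology knobs (QRS width, amplitudes, P-wave presence);
they emulate the variety of MLII beat shapes for testing purposes and
make no claim of clinical fidelity.  Ventricular classes (V, E) get wide
QRS complexes, bundle-branch blocks (L, R) intermediate widths, and
junctional/escape classes lose their P wave.

Contaminants (mains sine, baseline wander, white noise) are added after
the clean truth is recorded, so truth never depends on noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _wfdb
from .annotate import Fiducials
from .io_formats import Beat, ClassMap, DEFAULT_CLASS_MAP, EcgRecord, map_symbol

__all__ = [
    "Wave",
    "BeatTemplate",
    "NoiseConfig",
    "SynthRecord",
    "TEMPLATES",
    "make_beat",
    "make_record",
    "write_as_wfdb",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian component: centre offset from R (s), sigma (s), amp (mV)."""

    offset_s: float
    width_s: float
    amp_mv: float


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat class as P/Q/R/S/T Gaussian components."""

    class12: str
    waves: dict[str, Wave]  # keys ⊆ {P, Q, R, S, T}; Q, R, S required

    def __post_init__(self) -> None:
        for name in ("Q", "R", "S"):
            if name not in self.waves:
                raise ValueError(f"template {self.class12}: missing {name} wave")
        q, r, s = self.waves["Q"], self.waves["R"], self.waves["S"]
        if not q.offset_s < r.offset_s < s.offset_s:
            raise ValueError("Q, R, S centres must be ordered")
        for w in self.waves.values():
            if w.width_s <= 0:
                raise ValueError("wave widths must be positive")
            if not np.isfinite(w.amp_mv):
                raise ValueError("wave amplitudes must be finite")

    @property
    def qrs_width_s(self) -> float:
        """Nominal Q-to-S span in seconds."""
        return self.waves["S"].offset_s - self.waves["Q"].offset_s

    def span(self) -> tuple[float, float]:
        """Time extent (s, relative to R) covering all components to 4σ."""
        lo = min(w.offset_s - 4 * w.width_s for w in self.waves.values())
        hi = max(w.offset_s + 4 * w.width_s for w in self.waves.values())
        return lo, hi


def _template(
    class12: str,
    qrs_width: float = 0.080,
    r_amp: float = 1.1,
    q_amp: float = -0.15,
    s_amp: float = -0.25,
    p_amp: float = 0.12,
    t_amp: float = 0.30,
    p_offset: float = -0.20,
) -> BeatTemplate:
    half = qrs_width / 2
    waves = {
        "Q": Wave(-half, qrs_width / 9, q_amp),
        "R": Wave(0.0, qrs_width / 7, r_amp),
        "S": Wave(half, qrs_width / 9, s_amp),
        "T": Wave(0.30, 0.060, t_amp),
    }
    if p_amp:
        waves["P"] = Wave(p_offset, 0.025, p_amp)
    return BeatTemplate(class12, waves)


#: Default morphology per class.  Width/amplitude/P-wave knobs are the
#: only class distinctions; all templates keep a positive (upright) R so
#: the R-top bounding-box rule applies.
TEMPLATES: dict[str, BeatTemplate] = {
    "N": _template("N"),
    "L": _template("L", qrs_width=0.130, r_amp=0.9, s_amp=-0.35),
    "R": _template("R", qrs_width=0.120, r_amp=1.0, s_amp=-0.45),
    "e": _template("e", p_amp=0.0, r_amp=0.8),
    "j": _template("j", p_amp=0.0, r_amp=0.95),
    "A": _template("A", p_offset=-0.16, p_amp=0.18),
    "a": _template("a", qrs_width=0.100, p_offset=-0.16, p_amp=0.10),
    "J": _template("J", p_amp=0.0, r_amp=1.05),
    "S": _template("S", p_amp=0.06, r_amp=0.9),
    "V": _template("V", qrs_width=0.140, r_amp=1.3, q_amp=-0.30,
                   s_amp=-0.50, p_amp=0.0, t_amp=-0.25),
    "E": _template("E", qrs_width=0.140, r_amp=1.0, q_amp=-0.25,
                   s_amp=-0.40, p_amp=0.0),
    "F": _template("F", qrs_width=0.110, r_amp=1.0, s_amp=-0.35),
}

#: An inverted-QRS template (negative R): deliberately violates the
#: upright-R assumption of the box rule, for exercising the degenerate
#: path.  Not part of the 12-class set.
INVERTED_TEMPLATE = BeatTemplate(
    "V",
    {
        "Q": Wave(-0.05, 0.012, 0.20),
        "R": Wave(0.0, 0.016, -1.2),
        "S": Wave(0.05, 0.012, 0.30),
        "T": Wave(0.30, 0.060, 0.25),
    },
)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive contaminants: mains sine, baseline-wander sine, white noise."""

    powerline_amp_mv: float = 0.0
    powerline_hz: float = 50.0
    wander_amp_mv: float = 0.0
    wander_hz: float = 0.3
    white_sd_mv: float = 0.0


@dataclass
class SynthRecord:
    """A generated record with per-beat ground truth."""

    record: EcgRecord
    truth_fiducials: list[Fiducials]
    truth_classes: list[str]
    noise: NoiseConfig
    clean_signal: np.ndarray  # pre-contamination trace, mV

    def beats(self, class_map: ClassMap = DEFAULT_CLASS_MAP) -> list[Beat]:
        """Truth as :class:`Beat` objects (symbol = class12 label)."""
        out = []
        for fid, cls in zip(self.truth_fiducials, self.truth_classes):
            c12, aami = map_symbol(cls, class_map)
            out.append(Beat(fid.r_sample, cls, c12, aami))
        return out


def _render(template: BeatTemplate, t: np.ndarray, amps: dict[str, float]) -> np.ndarray:
    x = np.zeros_like(t)
    for name, w in template.waves.items():
        x += amps[name] * np.exp(-0.5 * ((t - w.offset_s) / w.width_s) ** 2)
    return x


def _argext_near(x: np.ndarray, center: int, halfwidth: int, sign: float) -> int:
    lo = max(0, center - halfwidth)
    hi = min(x.size, center + halfwidth + 1)
    seg = sign * x[lo:hi]
    return lo + int(np.argmax(seg))


def _truth_from_rendered(
    x: np.ndarray, template: BeatTemplate, fs: float, r_index_of_zero: int
) -> Fiducials:
    """Arg-extrema of the rendered trace near each QRS component centre."""
    idx = {}
    for name, sign in (("Q", -1.0), ("R", 1.0), ("S", -1.0)):
        w = template.waves[name]
        if name != "R" and w.amp_mv > 0:
            sign = 1.0
        center = r_index_of_zero + int(round(w.offset_s * fs))
        halfwidth = max(2, int(round(2 * w.width_s * fs)))
        idx[name] = _argext_near(x, center, halfwidth, sign)
    if template.waves["R"].amp_mv < 0:
        idx["R"] = _argext_near(
            x, r_index_of_zero, max(2, int(round(2 * template.waves["R"].width_s * fs))),
            -1.0,
        )
    return Fiducials(idx["Q"], idx["R"], idx["S"])


def make_beat(
    template: BeatTemplate,
    fs: float = 360.0,
    seed: int | None = None,
    amp_jitter: float = 0.0,
) -> tuple[np.ndarray, Fiducials]:
    """Render one beat; returns (samples, Fiducials relative to sample 0).

    ``amp_jitter`` scales each wave amplitude by N(1, jitter) (seeded);
    the returned fiducials are recomputed from the rendered waveform, so
    they stay exact under jitter.  Deterministic given (seed, config).
    """
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz to resolve QRS transients")
    lo, hi = template.span()
    n_before = int(np.ceil(-lo * fs))
    n_after = int(np.ceil(hi * fs))
    t = (np.arange(-n_before, n_after + 1)) / fs
    amps = {name: w.amp_mv for name, w in template.waves.items()}
    if amp_jitter > 0:
        rng = np.random.default_rng(seed)
        for name in amps:
            amps[name] *= 1.0 + amp_jitter * rng.standard_normal()
    x = _render(template, t, amps)
    fid = _truth_from_rendered(x, template, fs, n_before)
    return x, fid


def make_record(
    n_beats: int,
    classes: str | list[str] = "N",
    rr_mean_s: float = 0.8,
    rr_sd_s: float = 0.05,
    fs: float = 360.0,
    noise: NoiseConfig = NoiseConfig(),
    seed: int | None = None,
    amp_jitter: float = 0.05,
    record_id: str = "synth",
    templates: dict[str, BeatTemplate] | None = None,
) -> SynthRecord:
    """Generate a single-lead record of ``n_beats`` beats.

    ``classes`` is a class label or sequence cycled over beats.  RR
    intervals are drawn from N(rr_mean, rr_sd) truncated below so that
    consecutive QRS complexes cannot overlap (an overlap error is raised
    if the requested mean leaves no room).  Contaminants from ``noise``
    are added only after the clean trace and truth are recorded.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    templates = templates or TEMPLATES
    if isinstance(classes, str):
        classes = [classes]
    seq = [classes[i % len(classes)] for i in range(n_beats)]
    for c in seq:
        if c not in templates:
            raise KeyError(f"no template for class {c!r}")

    rng = np.random.default_rng(seed)
    min_rr = max(
        templates[a].qrs_width_s / 2 + templates[b].qrs_width_s / 2 + 0.05
        for a, b in zip(seq, seq[1:])
    ) if n_beats > 1 else 0.0
    if n_beats > 1 and rr_mean_s < min_rr:
        raise ValueError(
            f"rr_mean_s={rr_mean_s} too short: adjacent QRS complexes of "
            f"these templates need at least {min_rr:.3f} s"
        )
    rr = rng.normal(rr_mean_s, rr_sd_s, size=max(0, n_beats - 1))
    rr = np.clip(rr, min_rr if n_beats > 1 else 0.0, None)

    margin_s = 0.8  # lead-in/out so edge beats keep full search windows
    r_times = margin_s + np.concatenate([[0.0], np.cumsum(rr)])
    duration = r_times[-1] + margin_s
    n = int(np.ceil(duration * fs)) + 1
    x = np.zeros(n)

    fiducials: list[Fiducials] = []
    for i, (cls, rt) in enumerate(zip(seq, r_times)):
        beat_seed = None if seed is None else int(
            (seed * 1_000_003 + i) % (2**31 - 1)
        )
        samples, fid = make_beat(templates[cls], fs, beat_seed, amp_jitter)
        start = int(round(rt * fs)) - fid.r_sample
        if start < 0 or start + samples.size > n:
            raise ValueError("beat extends past record bounds")
        x[start : start + samples.size] += samples
        fiducials.append(
            Fiducials(start + fid.q_sample, start + fid.r_sample, start + fid.s_sample)
        )

    clean = x.copy()
    t = np.arange(n) / fs
    if noise.powerline_amp_mv:
        x = x + noise.powerline_amp_mv * np.sin(2 * np.pi * noise.powerline_hz * t)
    if noise.wander_amp_mv:
        x = x + noise.wander_amp_mv * np.sin(2 * np.pi * noise.wander_hz * t)
    if noise.white_sd_mv:
        x = x + noise.white_sd_mv * rng.standard_normal(n)

    record = EcgRecord(record_id, fs, ["MLII"], x.reshape(-1, 1))
    return SynthRecord(record, fiducials, seq, noise, clean)


def write_as_wfdb(
    sr: SynthRecord,
    directory,
    record_name: str | None = None,
    gain: float = 200.0,
) -> str:
    """Write the record as WFDB header/signal/annotation files.

    Amplitudes are quantized to ADC units at the given gain (the only
    loss in the round trip).  Beat symbols are the class12 labels, which
    coincide with WFDB beat annotation symbols.
    """
    record_name = record_name or sr.record.record_id
    adc = np.round(sr.record.signal * gain).astype(np.int32)
    _wfdb.write_record(
        directory, record_name, adc, sr.record.fs, list(sr.record.leads), gain=gain
    )
    anns = [
        (fid.r_sample, cls)
        for fid, cls in zip(sr.truth_fiducials, sr.truth_classes)
    ]
    _wfdb.write_annotations(f"{directory}/{record_name}.atr", anns)
    return record_name
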
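"""Record/annotation I/O and class taxonomies for beat-level ECG analysis.

Reads WFDB records (MIT-BIH style, lead MLII by default) into mV arrays,
reads beat annotations, maps WFDB beat symbols onto a 12-class scheme
(N, L, R, e, j, A, a, J, S, V, E, F) and the AAMI 5-group taxonomy
(N, SVEB, VEB, F, Q), and reads/writes Pascal-VOC style XML bounding-box
annotation files plus CSV dataset manifests.

Sample indices are 0-based everywhere in memory; VOC XML corners are
written 1-based inclusive (the common VOC dialect) and converted back on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from . import _wfdb

__all__ = [
    "EcgRecord",
    "Beat",
    "ClassMap",
    "VocAnnotation",
    "VocObject",
    "LeadNotFoundError",
    "DEFAULT_CLASS_MAP",
    "PACED_RECORDS",
    "read_record",
    "read_beats",
    "map_symbol",
    "read_voc",
    "write_voc",
    "read_manifest",
    "write_manifest",
]


class LeadNotFoundError(KeyError):
    """Requested lead name is absent from the record."""


#: MIT-BIH records paced with an artificial pacemaker; excluded by default.
PACED_RECORDS = ("102", "104", "107", "217")


@dataclass
class EcgRecord:
    """A sampled multi-lead ECG record in physical units (mV)."""

    record_id: str
    fs: float
    leads: list[str]
    signal: np.ndarray  # shape (n_samples, n_leads), mV

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] == 1 and len(self.leads) == 1:
            self.signal = self.signal.reshape(-1, 1)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[1] != len(self.leads):
            raise ValueError("signal columns must match lead names")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def lead(self, name: str) -> np.ndarray:
        """1-D mV trace of a single lead."""
        if name not in self.leads:
            raise LeadNotFoundError(
                f"lead {name!r} not in record {self.record_id!r} "
                f"(has {self.leads})"
            )
        return self.signal[:, self.leads.index(name)]


@dataclass(frozen=True)
class Beat:
    """One annotated heartbeat."""

    r_sample: int  # 0-based R-peak sample index
    symbol: str  # WFDB annotation character
    class12: str | None  # one of the 12 labels, or None if outside scheme
    aami5: str | None  # N / SVEB / VEB / F / Q, or None


@dataclass(frozen=True)
class ClassMap:
    """Symbol → 12-class and 12-class → AAMI-group lookup tables.

    Foreground class ids are 1..C in ``class12_order`` order; id 0 is
    reserved for the detector's background class.
    """

    symbol_to_class12: dict[str, str]
    class12_to_aami: dict[str, str]
    symbol_to_aami_extra: dict[str, str] = field(default_factory=dict)

    @property
    def class12_order(self) -> list[str]:
        return list(self.symbol_to_class12.values())

    @property
    def n_classes(self) -> int:
        return len(self.symbol_to_class12)

    def class_id(self, class12: str) -> int:
        """1-based foreground class id (0 is background)."""
        return self.class12_order.index(class12) + 1

    def aami_of(self, class12: str) -> str:
        return self.class12_to_aami[class12]


#: The 12 foreground beat classes and their AAMI groups.  Lowercase e/j/a
#: are the WFDB atrial-escape, nodal-escape and aberrated-APB symbols;
#: uppercase E is ventricular escape.  Paced (/), paced-fusion (f) and
#: unclassifiable (Q) beats fall outside the 12-class scheme and map only
#: to the AAMI "Q" (unknown) group.
DEFAULT_CLASS_MAP = ClassMap(
    symbol_to_class12={
        "N": "N", "L": "L", "R": "R", "e": "e", "j": "j", "A": "A",
        "a": "a", "J": "J", "S": "S", "V": "V", "E": "E", "F": "F",
    },
    class12_to_aami={
        "N": "N", "L": "N", "R": "N",
        "e": "SVEB", "j": "SVEB", "A": "SVEB", "a": "SVEB",
        "J": "SVEB", "S": "SVEB",
        "V": "VEB", "E": "VEB",
        "F": "F",
    },
    symbol_to_aami_extra={"/": "Q", "f": "Q", "Q": "Q"},
)


def map_symbol(
    symbol: str, class_map: ClassMap = DEFAULT_CLASS_MAP
) -> tuple[str | None, str | None]:
    """Map a WFDB beat symbol to (class12, aami5); None when outside scheme.

    Total function: unknown symbols map to (None, None).
    """
    class12 = class_map.symbol_to_class12.get(symbol)
    if class12 is not None:
        return class12, class_map.class12_to_aami[class12]
    return None, class_map.symbol_to_aami_extra.get(symbol)


# -- WFDB reading ------------------------------------------------------

def read_record(path: str | Path, lead: str | None = "MLII") -> EcgRecord:
    """Read a WFDB record (header path or stem) in mV.

    ``lead`` selects a single lead (MIT-BIH analyses conventionally use
    MLII); ``None`` keeps all leads.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    header = _wfdb.read_header(hea)
    adc = _wfdb.read_signal(header, hea.parent)
    gains = np.array([s.gain for s in header.signals])
    baselines = np.array([s.baseline for s in header.signals])
    signal = (adc - baselines) / gains  # ADC → mV
    leads = [s.description for s in header.signals]
    if lead is not None:
        if lead not in leads:
            raise LeadNotFoundError(
                f"lead {lead!r} not in record {header.record_name!r} "
                f"(has {leads})"
            )
        j = leads.index(lead)
        signal = signal[:, [j]]
        leads = [lead]
    return EcgRecord(header.record_name, header.fs, leads, signal)


def read_beats(
    path: str | Path,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
    n_samples: int | None = None,
) -> list[Beat]:
    """Read beat annotations (.atr) as an ordered list of :class:`Beat`.

    Non-beat annotations (rhythm changes, signal-quality marks) are
    excluded.  Beats are strictly ordered by sample; duplicates rejected.
    """
    path = Path(path)
    if path.suffix == "":
        path = path.with_suffix(".atr")
    anns = _wfdb.read_annotations(path)
    beats: list[Beat] = []
    prev = -1
    for sample, symbol in anns:
        code = _wfdb.SYMBOL_TO_CODE.get(symbol)
        if code not in _wfdb.BEAT_CODES:
            continue
        if sample <= prev:
            raise ValueError(
                f"beat annotations not strictly increasing at sample {sample}"
            )
        if n_samples is not None and not 0 <= sample < n_samples:
            raise ValueError(f"beat sample {sample} outside record")
        class12, aami5 = map_symbol(symbol, class_map)
        beats.append(Beat(sample, symbol, class12, aami5))
        prev = sample
    return beats


# -- VOC XML -----------------------------------------------------------

@dataclass(frozen=True)
class VocObject:
    name: str  # class12 label
    xmin: int
    ymin: int
    xmax: int
    ymax: int  # 0-based corners, xmin < xmax, ymin < ymax


@dataclass
class VocAnnotation:
    filename: str
    width: int
    height: int
    objects: list[VocObject]

    def validate(self) -> None:
        for o in self.objects:
            if not (o.xmin < o.xmax and o.ymin < o.ymax):
                raise ValueError(f"degenerate box in {self.filename}: {o}")
            if not (0 <= o.xmin and o.xmax < self.width
                    and 0 <= o.ymin and o.ymax < self.height):
                raise ValueError(f"box outside image bounds: {o}")


def write_voc(ann: VocAnnotation, path: str | Path) -> None:
    """Write a VOC-style XML file (corners stored 1-based inclusive)."""
    ann.validate()
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = ann.filename
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for o in ann.objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = o.name
        etree.SubElement(obj, "difficult").text = "0"
        box = etree.SubElement(obj, "bndbox")
        etree.SubElement(box, "xmin").text = str(o.xmin + 1)
        etree.SubElement(box, "ymin").text = str(o.ymin + 1)
        etree.SubElement(box, "xmax").text = str(o.xmax + 1)
        etree.SubElement(box, "ymax").text = str(o.ymax + 1)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, encoding="utf-8")


def read_voc(path: str | Path) -> VocAnnotation:
    """Parse a VOC-style XML file back into a :class:`VocAnnotation`."""
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML {path}: {exc}") from exc

    def _text(parent, tag):
        el = parent.find(tag)
        if el is None or el.text is None:
            raise ValueError(f"VOC XML {path}: missing <{tag}>")
        return el.text

    size = root.find("size")
    if size is None:
        raise ValueError(f"VOC XML {path}: missing <size>")
    ann = VocAnnotation(
        filename=_text(root, "filename"),
        width=int(_text(size, "width")),
        height=int(_text(size, "height")),
        objects=[],
    )
    for obj in root.findall("object"):
        box = obj.find("bndbox")
        if box is None:
            raise ValueError(f"VOC XML {path}: object without <bndbox>")
        ann.objects.append(
            VocObject(
                name=_text(obj, "name"),
                xmin=int(_text(box, "xmin")) - 1,
                ymin=int(_text(box, "ymin")) - 1,
                xmax=int(_text(box, "xmax")) - 1,
                ymax=int(_text(box, "ymax")) - 1,
            )
        )
    ann.validate()
    return ann


# -- manifests ---------------------------------------------------------

MANIFEST_COLUMNS = ["image", "annotation", "classes", "split"]


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
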
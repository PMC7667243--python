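"""Panel definition, event containers, FCS/CSV I/O, transforms and scatter QC.

The PIDOT screening panel measures three light-scatter parameters (FSC-A,
FSC-H, SSC-A) and eleven surface markers on a single tube.  Everything
downstream (simulation, manual gating, automated gating) consumes the
:class:`EventMatrix` defined here: an N x C matrix of compensated intensities
with the panel and sample metadata attached.

Raw intensities live on the instrument channel scale [0, 262144] (18-bit
digitizer convention).  Fluorescence channels can be mapped onto a standardized
display scale with ``asinh(x / cofactor)``; scatter channels are never
transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._errors import (
    FormatError,
    InsufficientEventsError,
    MappingError,
    MetadataError,
    ParameterError,
)

RAW_MAX = 262144.0  # 18-bit instrument channel ceiling

#: Scatter QC acceptance windows for lymphocyte-gated events (strict bounds).
FSC_QC_BOUNDS = (50_000.0, 60_000.0)
SSC_QC_BOUNDS = (11_000.0, 13_000.0)

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")
PIDOT_MARKERS = (
    "CD45", "CD3", "CD19", "CD16&CD56", "CD4", "CD8",
    "TCRgd", "CD27", "CD45RA", "IgM", "IgD",
)


@dataclass(frozen=True)
class Channel:
    """One cytometer channel: a short name, the marker it reads, and its kind."""

    name: str
    marker: str
    kind: str  # "scatter" | "fluorescence"

    def __post_init__(self) -> None:
        if self.kind not in ("scatter", "fluorescence"):
            raise ParameterError(f"unknown detector kind {self.kind!r}")


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered channel layout of one staining tube."""

    channels: tuple[Channel, ...]
    version: str = "custom"

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ParameterError("channel short names must be unique")
        if self.version == "pidot-v1":
            expected = set(SCATTER_CHANNELS) | set(PIDOT_MARKERS)
            if set(names) != expected:
                missing = expected - set(names)
                extra = set(names) - expected
                raise ParameterError(
                    f"pidot-v1 panel mismatch (missing={sorted(missing)}, "
                    f"extra={sorted(extra)})"
                )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise MappingError(f"channel {name!r} not in panel") from None

    @property
    def scatter_idx(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.kind == "scatter"])

    @property
    def fluor_idx(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channels) if c.kind == "fluorescence"]
        )

    @property
    def fluorescence_names(self) -> list[str]:
        return [c.name for c in self.channels if c.kind == "fluorescence"]


def pidot_panel() -> PanelDefinition:
    """The 14-channel PIDOT v1 panel (3 scatter + 11 markers).

    CD16 and CD56 are read on a single combined detector and are therefore a
    single channel, exactly as reported on clinical PIDOT tubes.
    """
    channels = [Channel(n, n.replace("-", " "), "scatter") for n in SCATTER_CHANNELS]
    channels += [Channel(m, m, "fluorescence") for m in PIDOT_MARKERS]
    return PanelDefinition(tuple(channels), version="pidot-v1")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata required for reporting absolute counts."""

    sample_id: str
    age_years: float
    wbc_per_ul: float
    group: str = "HD"  # HD | CVID | PID | nonPID

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_years <= 120.0):
            raise MetadataError(f"age_years {self.age_years} outside [0, 120]")
        if not (100.0 < self.wbc_per_ul < 500_000.0):
            raise MetadataError(f"wbc_per_ul {self.wbc_per_ul} outside (100, 500000)")
        if self.group not in ("HD", "CVID", "PID", "nonPID"):
            raise MetadataError(f"unknown group {self.group!r}")


@dataclass
class EventMatrix:
    """N x C event intensities plus panel and sample metadata.

    ``scale`` is ``"raw"`` (instrument units) or ``"transformed"`` (asinh
    standardized units on fluorescence channels; scatter always stays raw).
    ``cofactor`` records the asinh cofactor once transformed, so raw values
    can be recovered exactly.
    """

    values: np.ndarray
    panel: PanelDefinition
    sample_meta: SampleMeta | None = None
    scale: str = "raw"
    cofactor: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ParameterError("values must be a non-empty N x C matrix")
        if self.values.shape[1] != self.panel.n_channels:
            raise ParameterError(
                f"C={self.values.shape[1]} != panel channel count "
                f"{self.panel.n_channels}"
            )
        if not np.isfinite(self.values).all():
            raise ParameterError("event matrix contains non-finite values")
        if self.scale not in ("raw", "transformed"):
            raise ParameterError(f"unknown scale {self.scale!r}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Column view for one channel by short name."""
        return self.values[:, self.panel.index(name)]

    def raw(self) -> "EventMatrix":
        """Return a raw-scale copy (inverts the asinh transform if needed)."""
        if self.scale == "raw":
            return self
        return inverse_transform(self)


@dataclass(frozen=True)
class QCReport:
    """Scatter quality of the lymphocyte gate of one sample."""

    median_fsc_a: float
    median_ssc_a: float

    @property
    def fsc_pass(self) -> bool:
        lo, hi = FSC_QC_BOUNDS
        return lo < self.median_fsc_a < hi

    @property
    def ssc_pass(self) -> bool:
        lo, hi = SSC_QC_BOUNDS
        return lo < self.median_ssc_a < hi


# ---------------------------------------------------------------------------
# Channel aliasing
# ---------------------------------------------------------------------------

def load_alias_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the channel alias table (alternate label -> canonical short name).

    Without a path, the table shipped with the package is used.  Keys are
    matched case-insensitively after stripping whitespace.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "channel_aliases.yaml"
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(k).strip().lower(): str(v) for k, v in raw.items()}


def _map_channel_names(
    file_names: Iterable[str],
    panel: PanelDefinition,
    alias_map: Mapping[str, str] | None,
) -> list[int]:
    """Column order that rearranges file channels into panel order.

    Raises :class:`MappingError` naming any unmapped or duplicated channel.
    """
    aliases = dict(alias_map) if alias_map is not None else load_alias_map()
    canonical: dict[str, int] = {}
    file_names = list(file_names)
    for j, name in enumerate(file_names):
        key = name.strip()
        target = key if key in panel.names else aliases.get(key.lower())
        if target is None:
            raise MappingError(
                f"file channel {name!r} cannot be mapped onto the panel"
            )
        if target in canonical:
            raise MappingError(f"channel {target!r} mapped twice")
        canonical[target] = j
    missing = [n for n in panel.names if n not in canonical]
    if missing:
        raise MappingError(f"panel channels missing from file: {missing}")
    return [canonical[n] for n in panel.names]


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 reading, FCS 3.1 writing
# ---------------------------------------------------------------------------

_DELIM = "/"


def _read_fcs(path: Path) -> tuple[list[str], np.ndarray]:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FormatError(f"{path}: truncated FCS header")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        t_start = int(blob[10:18])
        t_end = int(blob[18:26])
    except ValueError as exc:
        raise FormatError(f"{path}: bad header offsets") from exc
    if t_end >= len(blob):
        raise FormatError(f"{path}: TEXT segment extends past end of file")
    text = blob[t_start : t_end + 1].decode("utf-8", "replace")
    delim, body = text[0], text[1:]
    parts = body.split(delim)
    kw = {
        parts[i].strip().upper(): parts[i + 1]
        for i in range(0, len(parts) - 1, 2)
        if parts[i].strip()
    }
    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        dtype_code = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
        d_start = int(kw.get("$BEGINDATA", blob[26:34]))
        d_end = int(kw.get("$ENDDATA", blob[34:42]))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing required FCS keywords") from exc
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) files are supported")
    names = []
    for i in range(1, n_par + 1):
        try:
            names.append(kw[f"$P{i}N"].strip())
        except KeyError as exc:
            raise FormatError(f"{path}: missing $P{i}N") from exc
    if dtype_code == "F":
        np_dtype, width = np.float32, 4
    elif dtype_code == "D":
        np_dtype, width = np.float64, 8
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    order = "<" if byteord.startswith("1") else ">"
    expected = n_tot * n_par * width
    data = blob[d_start : d_end + 1]
    if len(data) < expected:
        raise FormatError(
            f"{path}: DATA segment holds {len(data)} bytes, expected {expected}"
        )
    arr = np.frombuffer(data[:expected], dtype=f"{order}{np_dtype().dtype.char}")
    return names, arr.astype(np.float64).reshape(n_tot, n_par)


def _read_csv(path: Path) -> tuple[list[str], np.ndarray]:
    # Package CSV dialect: header of channel short names, one event per row.
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    if frame.shape[0] < 1:
        raise FormatError(f"{path}: CSV contains no events")
    return list(frame.columns), frame.to_numpy(dtype=np.float64)


def read_events(
    path: str | Path,
    panel: PanelDefinition,
    alias_map: Mapping[str, str] | None = None,
) -> EventMatrix:
    """Read an FCS 3.0/3.1 or package-dialect CSV file into an EventMatrix.

    File channels are mapped onto the panel by short name, falling back to the
    alias table; unmapped channels are an error, never silently dropped.
    Event order is preserved.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        names, values = _read_csv(path)
    else:
        names, values = _read_fcs(path)
    order = _map_channel_names(names, panel, alias_map)
    return EventMatrix(values[:, order], panel=panel, scale="raw")


def write_events(events: EventMatrix, path: str | Path) -> Path:
    """Write a raw-scale EventMatrix as FCS 3.1 (or CSV if path ends in .csv).

    The FCS file sets $PnN to the channel short names and $TOT to N;
    :func:`read_events` inverts it (values within float32 precision).
    """
    path = Path(path)
    if events.scale != "raw":
        raise ParameterError("write_events requires a raw-scale EventMatrix")
    if path.suffix.lower() == ".csv":
        frame = pd.DataFrame(events.values, columns=events.panel.names)
        frame.to_csv(path, index=False)
        return path

    n, c = events.values.shape
    data = events.values.astype("<f4").tobytes()
    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(c),
        "$TOT": str(n),
    }
    for i, ch in enumerate(events.panel.channels, start=1):
        kw[f"$P{i}N"] = ch.name
        kw[f"$P{i}S"] = ch.marker
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(RAW_MAX))

    header_len = 58
    # Two-pass layout: offsets depend on TEXT length, which contains offsets.
    def build_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        body = _DELIM + _DELIM.join(
            f"{k}{_DELIM}{v}" for k, v in sorted(items.items())
        ) + _DELIM
        return body.encode("utf-8")

    text = build_text(0, 0)
    for _ in range(3):  # converges once offset digit counts stabilize
        t_start = header_len
        t_end = t_start + len(text) - 1
        d_start = t_end + 1
        d_end = d_start + len(data) - 1
        new_text = build_text(d_start, d_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    header = b"FCS3.1    " + (
        f"{t_start:>8d}{t_end:>8d}{d_start:>8d}{d_end:>8d}{0:>8d}{0:>8d}"
        .encode("ascii")
    )
    assert len(header) == header_len, "malformed FCS header block"
    try:
        with open(path, "wb") as fh:
            fh.write(header + text + data)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Intensity transform
# ---------------------------------------------------------------------------

def transform_fluorescence(events: EventMatrix, cofactor: float = 150.0) -> EventMatrix:
    """Map fluorescence channels to ``asinh(x / cofactor)``; scatter untouched.

    The transform is strictly monotone per channel and exactly invertible via
    :func:`inverse_transform`.
    """
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    if events.scale != "raw":
        raise ParameterError("events already transformed")
    values = events.values.copy()
    fi = events.panel.fluor_idx
    values[:, fi] = np.arcsinh(values[:, fi] / cofactor)
    return EventMatrix(
        values,
        panel=events.panel,
        sample_meta=events.sample_meta,
        scale="transformed",
        cofactor=cofactor,
    )


def inverse_transform(events: EventMatrix) -> EventMatrix:
    """Recover raw channel units from a transformed EventMatrix."""
    if events.scale != "transformed":
        raise ParameterError("events are not transformed")
    values = events.values.copy()
    fi = events.panel.fluor_idx
    values[:, fi] = np.sinh(values[:, fi]) * events.cofactor
    return EventMatrix(
        values, panel=events.panel, sample_meta=events.sample_meta, scale="raw"
    )


# ---------------------------------------------------------------------------
# Scatter QC
# ---------------------------------------------------------------------------

def scatter_qc(events: EventMatrix, lymphocyte_mask: np.ndarray) -> QCReport:
    """Median FSC-A / SSC-A over the lymphocyte gate, checked against the
    recommended acceptance windows (median FSC-A in (50000, 60000), median
    SSC-A in (11000, 13000), both strict).

    Violations of these windows are associated with inflated manual-vs-
    automated count discrepancies, so the report should be consulted before a
    sample enters a method comparison.
    """
    mask = np.asarray(lymphocyte_mask, dtype=bool)
    if mask.shape != (events.n_events,):
        raise ParameterError("mask length must equal event count")
    n = int(mask.sum())
    if n < 100:
        raise InsufficientEventsError(
            f"scatter QC needs >=100 lymphocyte-gated events, got {n}"
        )
    fsc = float(np.median(events.channel("FSC-A")[mask]))
    ssc = float(np.median(events.channel("SSC-A")[mask]))
    return QCReport(median_fsc_a=fsc, median_ssc_a=ssc)
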
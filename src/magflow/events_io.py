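"""Flow-cytometry event tables and their on-disk formats.

The instrument model here is a single-laser benchtop cytometer (BD Accuri C6
class) with forward scatter (FSC-A), side scatter (SSC-A) and three
fluorescence detectors: FL1-A (green, 533/30 band-pass — BOX, Pyr-546,
PG-SK, Syto9), FL3-A (red, 670 long-pass — propidium iodide) and FL4-A
(far-red, 675/25 band-pass — Syto62). Intensities are kept on the linear
scale everywhere; log transforms happen in the gating module at use time.

Two interchange formats are supported:

* **FCS** — the writer emits FCS 3.1, single dataset, little-endian 32-bit
  float data segment, ``$PnE = 0,0`` (linear). The reader accepts FCS 3.0
  and 3.1 with float, double or integer data in either byte order.
* **CSV** — comma-separated with a header row naming the channels exactly
  as in the :class:`ChannelMap`; acquisition metadata travels in
  ``#key=value`` comment lines before the header. An optional trailing
  ``true_label`` column (synthetic data only) is preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ChannelError, FormatError, MetadataError, ValidationError

#: Canonical channel layout of the single-laser instrument.
DEFAULT_CHANNELS: tuple[str, ...] = ("FSC_A", "SSC_A", "FL1_A", "FL3_A", "FL4_A")

#: Sentinel recorded when an acquisition-metadata field is unknown.
UNKNOWN = None


def _normalise_channel(name: str) -> str:
    """Map instrument spellings (``FSC-A``) onto the package spelling (``FSC_A``)."""
    return name.strip().replace("-", "_")


@dataclass(frozen=True)
class ChannelMap:
    """Ordered detector channels of an event table.

    Channel *i* of :attr:`names` is column *i* of the intensity matrix;
    names are unique and FSC_A/SSC_A are always present.
    """

    names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        names = tuple(_normalise_channel(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate channel names: {names}")
        for required in ("FSC_A", "SSC_A"):
            if required not in names:
                raise ChannelError(f"channel map must contain {required}; got {names}")

    def index(self, name: str) -> int:
        name = _normalise_channel(name)
        try:
            return self.names.index(name)
        except ValueError:
            raise ChannelError(f"channel {name!r} not in {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return _normalise_channel(name) in self.names

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class AcquisitionMeta:
    """Acquisition metadata attached to an event table.

    ``flow_rate`` is in µL·min⁻¹ (the workflows here run the instrument at
    35 µL·min⁻¹), ``duration`` in seconds, ``dilution_factor`` is ≥ 1.
    Fields that were not recorded are ``None`` and listed in ``assumed`` so
    downstream volumetric arithmetic can refuse to guess.
    """

    n_events: int = 0
    flow_rate: float | None = 35.0
    duration: float | None = UNKNOWN
    dilution_factor: float | None = 1.0
    instrument_id: str = ""
    assumed: tuple[str, ...] = ()
    retained_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValidationError("n_events must be >= 0")
        if self.flow_rate is not None and self.flow_rate <= 0:
            raise ValidationError("flow_rate must be > 0")
        if self.duration is not None and self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.dilution_factor is not None and self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")

    def require(self, *fields_: str) -> None:
        """Raise :class:`MetadataError` if any named field is unknown or assumed."""
        for f in fields_:
            if getattr(self, f) is None:
                raise MetadataError(f"acquisition metadata field {f!r} is not set")
            if f in self.assumed:
                raise MetadataError(f"acquisition metadata field {f!r} is assumed, not measured")


@dataclass
class EventTable:
    """n_events × n_channels matrix of linear-scale intensities.

    All intensities are finite and non-negative. ``true_label`` carries the
    generating subpopulation of each event for synthetic data and is absent
    for instrument data.
    """

    data: np.ndarray
    channel_map: ChannelMap = field(default_factory=ChannelMap)
    meta: AcquisitionMeta | None = None
    true_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            self.data = self.data.reshape(-1, len(self.channel_map))
        if self.data.shape[1] != len(self.channel_map):
            raise ValidationError(
                f"data has {self.data.shape[1]} columns but channel map has "
                f"{len(self.channel_map)} channels"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite intensity at row {r}, channel {self.channel_map.names[c]}"
            )
        neg = self.data < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative intensity at row {r}, channel {self.channel_map.names[c]}"
            )
        if self.meta is None:
            self.meta = AcquisitionMeta(n_events=len(self.data))
        if self.meta.n_events != len(self.data):
            raise ValidationError(
                f"meta.n_events={self.meta.n_events} but table has {len(self.data)} rows"
            )
        if self.true_label is not None:
            self.true_label = np.asarray(self.true_label, dtype=object)
            if len(self.true_label) != len(self.data):
                raise ValidationError("true_label length must equal the event count")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        """Column of intensities for one detector channel."""
        return self.data[:, self.channel_map.index(name)]

    def select(self, mask: np.ndarray) -> "EventTable":
        """Subset of events; acquisition metadata is copied with n_events updated."""
        mask = np.asarray(mask, dtype=bool)
        meta = replace(self.meta, n_events=int(mask.sum()))
        labels = self.true_label[mask] if self.true_label is not None else None
        return EventTable(self.data[mask], self.channel_map, meta, labels)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.data, columns=list(self.channel_map.names))
        if self.true_label is not None:
            df["true_label"] = self.true_label
        return df


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("flow_rate", "duration", "dilution_factor", "instrument_id")


def _write_csv(table: EventTable, path: str) -> None:
    lines: list[str] = []
    m = table.meta
    for key in _META_KEYS:
        value = getattr(m, key)
        if value is not None and value != "":
            lines.append(f"#{key}={value}")
    if m.assumed:
        lines.append("#assumed=" + ",".join(m.assumed))
    header = list(table.channel_map.names)
    if table.true_label is not None:
        header.append("true_label")
    lines.append(",".join(header))
    for i in range(table.n_events):
        row = [format(v, ".10g") for v in table.data[i]]
        if table.true_label is not None:
            row.append(str(table.true_label[i]))
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_csv(path: str) -> EventTable:
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta_kv[k.strip()] = v.strip()
                continue
            if header is None:
                header = [h.strip() for h in line.split(",")]
            else:
                rows.append(line.split(","))
    if header is None:
        raise FormatError(f"{path}: no header row found")

    has_label = header[-1] == "true_label"
    channel_names = header[:-1] if has_label else header
    if not channel_names:
        raise FormatError(f"{path}: no recognisable channels in header")
    channel_map = ChannelMap(tuple(channel_names))

    n = len(rows)
    data = np.empty((n, len(channel_names)), dtype=np.float64)
    labels = np.empty(n, dtype=object) if has_label else None
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise FormatError(f"{path}: row {i} has {len(row)} fields, expected {len(header)}")
        for j in range(len(channel_names)):
            try:
                data[i, j] = float(row[j])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {row[j]!r} at row {i}, "
                    f"channel {channel_names[j]}"
                ) from None
        if has_label:
            labels[i] = row[-1]

    assumed = tuple(
        k for k in meta_kv.get("assumed", "").split(",") if k
    )
    meta = AcquisitionMeta(
        n_events=n,
        flow_rate=float(meta_kv["flow_rate"]) if "flow_rate" in meta_kv else None,
        duration=float(meta_kv["duration"]) if "duration" in meta_kv else None,
        dilution_factor=float(meta_kv["dilution_factor"]) if "dilution_factor" in meta_kv else None,
        instrument_id=meta_kv.get("instrument_id", ""),
        assumed=assumed,
    )
    return EventTable(data, channel_map, meta, labels)


# ---------------------------------------------------------------------------
# FCS 3.0/3.1
# ---------------------------------------------------------------------------

_FCS_DELIM = "/"


def _write_fcs(table: EventTable, path: str) -> None:
    """Emit FCS 3.1: one dataset, little-endian float32, $PnE = 0,0."""
    n_par = len(table.channel_map)
    n_tot = table.n_events
    data = table.data.astype("<f4")
    data_bytes = data.tobytes(order="C")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        # placeholders; fixed-width so TEXT length is offset-independent
        ("$BEGINDATA", "%12d"),
        ("$ENDDATA", "%12d"),
        ("$NEXTDATA", "0"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    m = table.meta
    if m.instrument_id:
        keywords.append(("$CYT", m.instrument_id))
    if m.flow_rate is not None:
        keywords.append(("MAGFLOW_FLOWRATE", format(m.flow_rate, ".10g")))
    if m.duration is not None:
        keywords.append(("MAGFLOW_DURATION", format(m.duration, ".10g")))
    if m.dilution_factor is not None:
        keywords.append(("MAGFLOW_DILUTION", format(m.dilution_factor, ".10g")))
    if m.assumed:
        keywords.append(("MAGFLOW_ASSUMED", ",".join(m.assumed)))
    for i, name in enumerate(table.channel_map.names, start=1):
        rng = float(table.data[:, i - 1].max()) if n_tot else 1.0
        keywords.append((f"$P{i}N", name.replace("_", "-")))
        keywords.append((f"$P{i}B", "32"))
        keywords.append((f"$P{i}E", "0,0"))
        keywords.append((f"$P{i}R", str(int(np.ceil(rng)) + 1)))

    def render_text(begin_data: int, end_data: int) -> bytes:
        parts = [_FCS_DELIM]
        for key, value in keywords:
            if key == "$BEGINDATA":
                value = "%12d" % begin_data
            elif key == "$ENDDATA":
                value = "%12d" % end_data
            parts.append(f"{key}{_FCS_DELIM}{value}{_FCS_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text_start = header_len
    text = render_text(0, 0)
    text_end = text_start + len(text) - 1
    begin_data = text_end + 1
    end_data = begin_data + len(data_bytes) - 1 if data_bytes else 0
    text = render_text(begin_data, end_data)  # same length: fixed-width values

    def offset_field(v: int) -> bytes:
        # header offset fields are 8 ASCII chars; 0 if the value does not fit
        s = str(v) if v <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(b"FCS3.1")
        fh.write(b" " * 4)
        fh.write(offset_field(text_start))
        fh.write(offset_field(text_end))
        fh.write(offset_field(begin_data if end_data else 0))
        fh.write(offset_field(end_data))
        fh.write(offset_field(0))  # analysis start
        fh.write(offset_field(0))  # analysis end
        fh.write(text)
        fh.write(data_bytes)


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def _read_fcs(path: str) -> EventTable:
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = buf[0:6].decode("latin-1")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")

    def header_offset(lo: int, hi: int) -> int:
        text = buf[lo:hi].decode("latin-1").strip()
        return int(text) if text else 0

    text_start = header_offset(10, 18)
    text_end = header_offset(18, 26)
    data_start = header_offset(26, 34)
    data_end = header_offset(34, 42)
    kw = _parse_fcs_text(buf[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"

    names = []
    widths = []
    for i in range(1, n_par + 1):
        names.append(_normalise_channel(kw.get(f"$P{i}N", f"P{i}")))
        widths.append(int(kw.get(f"$P{i}B", "32")))

    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
        itemsizes = [4] * n_par
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
        itemsizes = [8] * n_par
    elif datatype == "I":
        if len(set(widths)) != 1:
            raise FormatError(f"{path}: mixed integer widths {widths} not supported")
        nbytes = widths[0] // 8
        if nbytes not in (2, 4):
            raise FormatError(f"{path}: unsupported integer width {widths[0]}")
        dtype = np.dtype(f"{endian}u{nbytes}")
        itemsizes = [nbytes] * n_par
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_tot * sum(itemsizes)
    raw = buf[data_start : data_end + 1] if expected else b""
    if len(raw) < expected:
        raise FormatError(
            f"{path}: data segment holds {len(raw)} bytes, expected {expected} "
            f"for {n_tot} events ({version})"
        )
    flat = np.frombuffer(raw[:expected], dtype=dtype)
    data = flat.reshape(n_tot, n_par).astype(np.float64) if n_tot else np.empty((0, n_par))

    assumed = tuple(k for k in kw.get("MAGFLOW_ASSUMED", "").split(",") if k)
    meta = AcquisitionMeta(
        n_events=n_tot,
        flow_rate=float(kw["MAGFLOW_FLOWRATE"]) if "MAGFLOW_FLOWRATE" in kw else None,
        duration=float(kw["MAGFLOW_DURATION"]) if "MAGFLOW_DURATION" in kw else None,
        dilution_factor=float(kw["MAGFLOW_DILUTION"]) if "MAGFLOW_DILUTION" in kw else None,
        instrument_id=kw.get("$CYT", ""),
        assumed=assumed,
    )
    return EventTable(data, ChannelMap(tuple(names)), meta)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_events(path: str, format: str = "csv") -> EventTable:
    """Read an event table from ``path``.

    Parameters
    ----------
    path:
        File written by :func:`write_events` or by an instrument.
    format:
        ``"fcs"`` (FCS 3.0/3.1) or ``"csv"`` (the package's commented CSV
        dialect).

    The full record count of the file is returned: events are never
    silently dropped. Negative or non-finite intensities raise
    :class:`~magflow.errors.ValidationError` naming the offending row and
    channel.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "fcs":
        return _read_fcs(path)
    raise FormatError(f"unknown format {format!r}; expected 'fcs' or 'csv'")


def write_events(table: EventTable, path: str, format: str = "csv") -> None:
    """Write ``table`` so that :func:`read_events` round-trips it.

    CSV preserves intensities to 10 significant digits and the
    ``true_label`` column verbatim. FCS stores intensities as 32-bit floats
    (round-trip within ~1e-7 relative); per-event labels are not
    representable in FCS and are dropped.
    """
    if format == "csv":
        _write_csv(table, path)
    elif format == "fcs":
        _write_fcs(table, path)
    else:
        raise FormatError(f"unknown format {format!r}; expected 'fcs' or 'csv'")
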
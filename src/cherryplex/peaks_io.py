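"""Reading and writing fragment-analysis peak tables.

Peaks arrive pre-sized (a size standard has already been fitted by the
instrument software); a peak is (dye channel, size in nt, height in RFU).
Two delimited-text dialects are supported:

* ``simple`` -- one peak per row with columns ``sample, dye, size, height``;
  comma- or tab-separated (sniffed from the header row);
* ``genemapper_export`` -- the tab-delimited genotypes-table export of
  common fragment-analysis software: one row per sample with a dye column
  and repeated ``Size N`` / ``Height N`` column pairs.

Dye strings are normalized case-insensitively from dye names ("6-FAM",
"VIC", ...), channel letters ("B", "G", "Y", "R") and color words ("blue",
"green", "yellow"/"black", "red").
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .panel import DyeChannel

Source = Union[str, os.PathLike, io.IOBase]


@dataclass(frozen=True)
class Peak:
    """One called peak from a capillary run."""

    channel: DyeChannel
    size: float
    height: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("peak size must be > 0")
        if self.height < 0:
            raise ValueError("peak height must be >= 0")


@dataclass
class SampleRun:
    """All peaks of one sample's capillary run."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    def channel_peaks(self, channel: DyeChannel) -> list[Peak]:
        return [p for p in self.peaks if p.channel == channel]


_DYE_MAP = {
    "b": DyeChannel.B, "blue": DyeChannel.B, "fam": DyeChannel.B,
    "6-fam": DyeChannel.B, "6fam": DyeChannel.B,
    "g": DyeChannel.G, "green": DyeChannel.G, "vic": DyeChannel.G,
    "y": DyeChannel.Y, "yellow": DyeChannel.Y, "ned": DyeChannel.Y,
    "black": DyeChannel.Y,
    "r": DyeChannel.R, "red": DyeChannel.R, "pet": DyeChannel.R,
}


def normalize_dye(value: str) -> DyeChannel:
    """Map a dye string to its channel; raises on unknown dyes."""
    key = str(value).strip().lower()
    if key not in _DYE_MAP:
        raise ValueError(f"unknown dye string: {value!r}")
    return _DYE_MAP[key]


def _as_text(source: Source) -> io.StringIO:
    if hasattr(source, "read"):
        return io.StringIO(source.read())
    text = Path(source).read_text()
    return io.StringIO(text)


def _find_column(columns: Iterable[str], *names: str) -> str | None:
    lowered = {str(c).strip().lower(): c for c in columns}
    for n in names:
        if n in lowered:
            return lowered[n]
    return None


def read_peak_table(source: Source, dialect: str = "simple") -> list[SampleRun]:
    """Parse a delimited peak table into one :class:`SampleRun` per sample.

    Samples appear in input order, as do their peaks.
    """
    if dialect == "simple":
        return _read_simple(source)
    if dialect == "genemapper_export":
        return _read_genemapper(source)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_simple(source: Source) -> list[SampleRun]:
    buf = _as_text(source)
    header = buf.readline()
    if not header.strip():
        return []
    sep = "\t" if "\t" in header else ","
    buf.seek(0)
    df = pd.read_csv(buf, sep=sep, dtype=str, skip_blank_lines=True)
    cols = {}
    for want in ("sample", "dye", "size", "height"):
        col = _find_column(df.columns, want)
        if col is None:
            raise ValueError(f"missing required column: {want!r}")
        cols[want] = col

    runs: dict[str, SampleRun] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        sample = str(row[cols["sample"]]).strip()
        channel = normalize_dye(row[cols["dye"]])
        try:
            size = float(row[cols["size"]])
            height = float(row[cols["height"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"line {line_no}: unparseable size/height "
                f"({row[cols['size']]!r}, {row[cols['height']]!r})"
            ) from exc
        runs.setdefault(sample, SampleRun(sample)).peaks.append(
            Peak(channel, size, height)
        )
    return list(runs.values())


def _read_genemapper(source: Source) -> list[SampleRun]:
    buf = _as_text(source)
    df = pd.read_csv(buf, sep="\t", dtype=str, skip_blank_lines=True)
    sample_col = _find_column(df.columns, "sample name", "sample file", "sample")
    if sample_col is None:
        raise ValueError("missing required column: 'Sample Name'")
    dye_col = _find_column(df.columns, "dye", "dye/sample peak")
    if dye_col is None:
        raise ValueError("missing required column: 'Dye'")

    size_cols = sorted(
        (c for c in df.columns if str(c).strip().lower().startswith("size")),
        key=lambda c: str(c),
    )
    height_cols = sorted(
        (c for c in df.columns if str(c).strip().lower().startswith("height")),
        key=lambda c: str(c),
    )
    if not size_cols or len(size_cols) != len(height_cols):
        raise ValueError("missing required column: paired 'Size n'/'Height n'")

    runs: dict[str, SampleRun] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2
        sample = str(row[sample_col]).strip()
        dye = str(row[dye_col]).strip()
        # "B" or "B,B" style annotations; first token carries the dye
        channel = normalize_dye(dye.split(",")[0])
        run = runs.setdefault(sample, SampleRun(sample))
        for sc, hc in zip(size_cols, height_cols):
            sval, hval = row[sc], row[hc]
            if pd.isna(sval) or str(sval).strip() == "":
                continue
            try:
                size = float(sval)
                height = float(hval)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"line {line_no}: unparseable size/height "
                    f"({sval!r}, {hval!r})"
                ) from exc
            run.peaks.append(Peak(channel, size, height))
    return list(runs.values())


def write_peak_table(runs: list[SampleRun], dialect: str = "simple",
                     sep: str = ",") -> str:
    """Serialize runs to the simple dialect (sizes to 2 decimals, heights to
    integer RFU); ``read_peak_table`` inverts it up to that rounding."""
    if dialect != "simple":
        raise ValueError(f"unsupported write dialect: {dialect!r}")
    lines = [sep.join(("sample", "dye", "size", "height"))]
    for run in runs:
        for p in run.peaks:
            lines.append(sep.join((
                run.sample_id,
                p.channel.value,
                f"{p.size:.2f}",
                str(int(round(p.height))),
            )))
    return "\n".join(lines) + "\n"
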
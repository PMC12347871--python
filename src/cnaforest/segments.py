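"""Segment-level chromosomal-microarray calls.

Domain types for CMA aberration segments (gains, losses, mosaic losses and
copy-neutral LOH), readers/writers for the tab-separated segment dialect and
for BED-like gene catalogs, and the validity filters applied before any
downstream analysis:

* a QC filter on SNP-marker support and mean log2-ratio, as used to validate
  calls exported from array-analysis software, and
* a size ("landscape") filter used only when reporting genome-wide aberration
  landscapes, not for feature encoding.

Internal coordinates are 1-based inclusive throughout, the native convention
of CMA segment tables; BED interchange converts at the file boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError

EVENT_TYPES = ("gain", "loss", "loss_mosaic", "cnLOH")

#: Canonical spellings accepted on input, after lower-casing and collapsing
#: spaces/hyphens to underscores.
_EVENT_ALIASES = {
    "gain": "gain",
    "loss": "loss",
    "loss_mosaic": "loss_mosaic",
    "mosaic_loss": "loss_mosaic",
    "cnloh": "cnLOH",
    "loh": "cnLOH",
}

SEGMENT_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "end",
    "event_type",
    "marker_count",
    "mean_log2ratio",
    "mosaic_fraction",
)

MISSING = "."


def normalize_event_type(raw: str) -> str:
    """Fold an event-type string to the canonical vocabulary.

    Case-insensitive; spaces, hyphens and underscores are equivalent
    ("Loss Mosaic", "LOSS-MOSAIC" and "loss_mosaic" all map to
    ``loss_mosaic``). Unknown strings raise :class:`ValidationError`.
    """
    key = re.sub(r"[\s\-]+", "_", raw.strip()).lower()
    try:
        return _EVENT_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown event type {raw!r}; expected one of {EVENT_TYPES}"
        ) from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def size_kb(self) -> float:
        return self.size_bp / 1000.0


@dataclass(frozen=True)
class AberrationSegment:
    """One CMA call: an interval, its event type, and its QC metrics.

    ``mean_log2ratio`` is absent (None) for cnLOH segments — copy-neutral
    events have no dosage signal by definition. ``mosaic_fraction`` is the
    estimated fraction of cells carrying the event, when reported.
    """

    sample_id: str
    interval: GenomicInterval
    event_type: str
    marker_count: int
    mean_log2ratio: float | None = None
    mosaic_fraction: float | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(
                f"event_type {self.event_type!r} not in {EVENT_TYPES}"
            )
        if self.marker_count < 0:
            raise ValidationError(
                f"marker_count must be >= 0, got {self.marker_count}"
            )
        if self.event_type == "cnLOH" and self.mean_log2ratio is not None:
            raise ValidationError(
                "cnLOH segments are copy-neutral and carry no mean_log2ratio"
            )
        if self.mosaic_fraction is not None and not (
            0.0 <= self.mosaic_fraction <= 1.0
        ):
            raise ValidationError(
                f"mosaic_fraction must be in [0,1], got {self.mosaic_fraction}"
            )

    @property
    def size_kb(self) -> float:
        return self.interval.size_kb


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus: symbol, interval, and cytoband label (e.g. '19q13.2')."""

    symbol: str
    interval: GenomicInterval
    band: str


@dataclass(frozen=True)
class QCThresholds:
    """Validity thresholds for CMA calls.

    Marker-count minima are inclusive (a call with exactly the threshold
    count is retained); dosage validity requires the mean log2-ratio to
    strictly exceed ``min_abs_log2ratio`` in magnitude, positive for gains
    and negative for losses. The landscape sizes are strict lower bounds
    ("exceeding") used only for genome-wide landscape reporting.
    """

    min_markers_loh: int = 50
    min_markers_gain: int = 50
    min_markers_loss: int = 20
    min_abs_log2ratio: float = 0.25
    min_cnv_kb_landscape: float = 500.0
    min_loh_kb_landscape: float = 5000.0

    def __post_init__(self):
        for name in (
            "min_markers_loh",
            "min_markers_gain",
            "min_markers_loss",
            "min_abs_log2ratio",
            "min_cnv_kb_landscape",
            "min_loh_kb_landscape",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def _parse_optional_float(text: str, what: str, line: int) -> float | None:
    if text == MISSING:
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"non-numeric {what}: {text!r}", line=line) from None


def read_segments(path: str | Path) -> list[AberrationSegment]:
    """Read a segment TSV (header required, '.' for absent values).

    Raises :class:`FormatError` naming the missing column if the header does
    not match the documented dialect, or with the line number for a row that
    cannot be parsed or violates a segment invariant.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        for col in SEGMENT_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in SEGMENT_COLUMNS}
        segments: list[AberrationSegment] = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise FormatError(
                    f"expected {len(header)} fields, got {len(parts)}",
                    line=lineno,
                )
            get = lambda col: parts[idx[col]]  # noqa: E731
            try:
                start = int(get("start"))
                end = int(get("end"))
                markers = int(get("marker_count"))
            except ValueError as exc:
                raise FormatError(f"non-numeric coordinate or count: {exc}",
                                  line=lineno) from None
            try:
                seg = AberrationSegment(
                    sample_id=get("sample_id"),
                    interval=GenomicInterval(get("chrom"), start, end),
                    event_type=normalize_event_type(get("event_type")),
                    marker_count=markers,
                    mean_log2ratio=_parse_optional_float(
                        get("mean_log2ratio"), "mean_log2ratio", lineno
                    ),
                    mosaic_fraction=_parse_optional_float(
                        get("mosaic_fraction"), "mosaic_fraction", lineno
                    ),
                )
            except ValidationError as exc:
                raise FormatError(str(exc), line=lineno) from None
            segments.append(seg)
    return segments


def _format_optional(value: float | None) -> str:
    return MISSING if value is None else repr(float(value))


def write_segments(segments: Iterable[AberrationSegment],
                   path: str | Path) -> None:
    """Write segments in the TSV dialect read by :func:`read_segments`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                "\t".join(
                    (
                        s.sample_id,
                        s.interval.chrom,
                        str(s.interval.start),
                        str(s.interval.end),
                        s.event_type,
                        str(s.marker_count),
                        _format_optional(s.mean_log2ratio),
                        _format_optional(s.mosaic_fraction),
                    )
                )
                + "\n"
            )


def qc_filter(
    segments: Sequence[AberrationSegment],
    thresholds: QCThresholds = QCThresholds(),
) -> list[AberrationSegment]:
    """Retain only segments that pass marker-count and log2-ratio validity.

    * cnLOH: ``marker_count >= min_markers_loh`` (no dosage criterion —
      copy-neutral by definition);
    * gain: ``marker_count >= min_markers_gain`` and
      ``mean_log2ratio > min_abs_log2ratio``;
    * loss / loss_mosaic: ``marker_count >= min_markers_loss`` and
      ``mean_log2ratio < -min_abs_log2ratio``.

    Pure selection: input order preserved, retained segments unmodified.
    A gain/loss segment lacking a mean log2-ratio cannot be validated and
    raises :class:`ValidationError`.
    """
    t = thresholds
    kept: list[AberrationSegment] = []
    for s in segments:
        if s.event_type == "cnLOH":
            if s.marker_count >= t.min_markers_loh:
                kept.append(s)
            continue
        if s.mean_log2ratio is None:
            raise ValidationError(
                f"{s.event_type} segment {s.sample_id} "
                f"{s.interval.chrom}:{s.interval.start}-{s.interval.end} "
                "has no mean_log2ratio; dosage validity cannot be assessed"
            )
        if s.event_type == "gain":
            if (s.marker_count >= t.min_markers_gain
                    and s.mean_log2ratio > t.min_abs_log2ratio):
                kept.append(s)
        else:  # loss, loss_mosaic
            if (s.marker_count >= t.min_markers_loss
                    and s.mean_log2ratio < -t.min_abs_log2ratio):
                kept.append(s)
    return kept


def landscape_filter(
    segments: Sequence[AberrationSegment],
    thresholds: QCThresholds = QCThresholds(),
) -> list[AberrationSegment]:
    """Size filter for genome-wide landscape reporting.

    Keeps gains/losses strictly exceeding ``min_cnv_kb_landscape`` and cnLOH
    strictly exceeding ``min_loh_kb_landscape``. Display-only: the feature
    encoding uses all QC-passed segments, not this subset.
    """
    t = thresholds
    out = []
    for s in segments:
        limit = (t.min_loh_kb_landscape if s.event_type == "cnLOH"
                 else t.min_cnv_kb_landscape)
        if s.size_kb > limit:
            out.append(s)
    return out


def read_gene_catalog(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene catalog: 5-column BED-like file (chrom, start, end,
    symbol, band), no header, standard BED coordinate semantics.

    On-disk 0-based half-open [start, end) becomes internal 1-based closed
    [start+1, end]. Duplicate symbols are rejected.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(
                    f"expected 5 columns (chrom start end symbol band), "
                    f"got {len(parts)}", line=lineno,
                )
            chrom, start_s, end_s, symbol, band = parts[:5]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-numeric coordinate", line=lineno) from None
            if end0 <= start0:
                raise FormatError(
                    f"BED end ({end0}) must be > start ({start0})", line=lineno
                )
            if symbol in seen:
                raise FormatError(f"duplicate gene symbol {symbol!r}",
                                  line=lineno)
            seen.add(symbol)
            genes.append(
                GeneAnnotation(symbol, GenomicInterval(chrom, start0 + 1, end0),
                               band)
            )
    return genes


def write_gene_catalog(genes: Iterable[GeneAnnotation],
                       path: str | Path) -> None:
    """Write a gene catalog in the BED-like dialect of
    :func:`read_gene_catalog` (coordinates converted back to 0-based
    half-open)."""
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start - 1}\t{g.interval.end}"
                f"\t{g.symbol}\t{g.band}\n"
            )
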
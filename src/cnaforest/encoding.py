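"""Gene-centric binary encoding of aberration segments.

Each feature is a (gene, canonical event) pair — "PSG1:cnLOH", "MT1A:loss" —
and a sample scores 1 on a feature when at least one of its QC-passed
segments of that canonical event overlaps the gene by one or more bases.
Mosaic losses are merged into plain losses before encoding, so a subclonal
and a clonal deletion of the same gene land in the same column. Only
(gene, event) pairs observed in at least one sample become columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .segments import AberrationSegment, GeneAnnotation, GenomicInterval

#: Canonical (post-merge) event vocabulary.
CANON_EVENTS = ("gain", "loss", "cnLOH")


def canonical_event(event_type: str) -> str:
    """Merge mosaic losses into losses; other event types pass through."""
    if event_type == "loss_mosaic":
        return "loss"
    if event_type not in CANON_EVENTS:
        raise ValidationError(f"unknown event type {event_type!r}")
    return event_type


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two 1-based closed intervals share >= 1 base."""
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


@dataclass(frozen=True)
class GeneEventFeature:
    """One encoded variable: a gene symbol and its canonical aberration."""

    symbol: str
    canon_event: str

    def __post_init__(self):
        if self.canon_event not in CANON_EVENTS:
            raise ValidationError(
                f"canon_event must be one of {CANON_EVENTS}, "
                f"got {self.canon_event!r}"
            )

    @property
    def id(self) -> str:
        return f"{self.symbol}:{self.canon_event}"

    @staticmethod
    def from_id(feature_id: str) -> "GeneEventFeature":
        symbol, _, event = feature_id.rpartition(":")
        return GeneEventFeature(symbol, event)


@dataclass
class GeneEventMatrix:
    """Samples x (gene, event) binary presence matrix.

    ``values`` is a dense uint8 array with entries in {0, 1}; rows follow
    ``sample_ids``, columns follow ``features`` (lexicographic by id).
    """

    sample_ids: list[str]
    features: list[GeneEventFeature]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        n, m = len(self.sample_ids), len(self.features)
        if self.values.shape != (n, m):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n}, {m})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("matrix entries must be 0 or 1")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        ids = [f.id for f in self.features]
        if len(set(ids)) != m:
            raise ValidationError("duplicate feature ids")
        self._col = {fid: j for j, fid in enumerate(ids)}

    @property
    def feature_ids(self) -> list[str]:
        return [f.id for f in self.features]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, feature_id: str) -> np.ndarray:
        """The 0/1 carrier vector for one feature, or zeros if absent."""
        j = self._col.get(feature_id)
        if j is None:
            return np.zeros(len(self.sample_ids), dtype=np.uint8)
        return self.values[:, j]

    def has_feature(self, feature_id: str) -> bool:
        return feature_id in self._col

    def constant_feature_ids(self) -> list[str]:
        """Ids of columns that are constant across samples (flagged, not
        forbidden)."""
        if not self.features:
            return []
        const = self.values.min(axis=0) == self.values.max(axis=0)
        return [f.id for f, c in zip(self.features, const) if c]

    @classmethod
    def from_arrays(
        cls,
        sample_ids: Sequence[str],
        feature_ids: Sequence[str],
        values,
    ) -> "GeneEventMatrix":
        feats = [GeneEventFeature.from_id(fid) for fid in feature_ids]
        return cls(list(sample_ids), feats, np.asarray(values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids),
            columns=self.feature_ids, copy=True,
        )

    # -- interchange -------------------------------------------------------

    def write_wide(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    def write_sparse(self, path: str | Path) -> None:
        """Coordinate-triplet TSV: sample_id, feature_id, value(=1)."""
        rows, cols = np.nonzero(self.values)
        with Path(path).open("w") as fh:
            fh.write("sample_id\tfeature_id\tvalue\n")
            for i, j in zip(rows, cols):
                fh.write(f"{self.sample_ids[i]}\t{self.features[j].id}\t1\n")

    @classmethod
    def read_wide(cls, path: str | Path) -> "GeneEventMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls.from_arrays(list(df.index.astype(str)),
                               list(df.columns), df.to_numpy())


def encode(
    segments: Sequence[AberrationSegment],
    catalog: Sequence[GeneAnnotation],
    sample_ids: Sequence[str],
) -> GeneEventMatrix:
    """Build the binary gene x event matrix from QC-passed segments.

    Rows follow ``sample_ids`` as given; columns are the (gene, canonical
    event) pairs observed in at least one sample, ordered lexicographically
    by feature id. Invariant to segment and catalog order; duplicate
    segments are idempotent. A segment whose sample is not in ``sample_ids``
    raises :class:`ValidationError`.
    """
    order = {sid: i for i, sid in enumerate(sample_ids)}
    if len(order) != len(sample_ids):
        raise ValidationError("duplicate sample ids")

    trees: dict[str, IntervalTree] = {}
    gene_of: dict[int, str] = {}
    for k, g in enumerate(catalog):
        # closed [start, end] -> half-open [start, end+1) for intervaltree
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end + 1, k
        )
        gene_of[k] = g.symbol

    hits: set[tuple[int, str, str]] = set()
    for s in segments:
        row = order.get(s.sample_id)
        if row is None:
            raise ValidationError(
                f"segment references unknown sample {s.sample_id!r}"
            )
        tree = trees.get(s.interval.chrom)
        if tree is None:
            continue
        ev = canonical_event(s.event_type)
        for iv in tree.overlap(s.interval.start, s.interval.end + 1):
            hits.add((row, gene_of[iv.data], ev))

    observed = sorted({(sym, ev) for _, sym, ev in hits},
                      key=lambda t: f"{t[0]}:{t[1]}")
    col = {pair: j for j, pair in enumerate(observed)}
    values = np.zeros((len(sample_ids), len(observed)), dtype=np.uint8)
    for row, sym, ev in hits:
        values[row, col[(sym, ev)]] = 1
    features = [GeneEventFeature(sym, ev) for sym, ev in observed]
    return GeneEventMatrix(list(sample_ids), features, values)


def write_feature_dictionary(
    features: Iterable[GeneEventFeature],
    catalog: Sequence[GeneAnnotation],
    path: str | Path,
) -> None:
    """Feature dictionary TSV: id, symbol, event, band."""
    band = {g.symbol: g.band for g in catalog}
    with Path(path).open("w") as fh:
        fh.write("id\tsymbol\tevent\tband\n")
        for f in features:
            fh.write(f"{f.id}\t{f.symbol}\t{f.canon_event}\t"
                     f"{band.get(f.symbol, MISSING_BAND)}\n")


MISSING_BAND = "."
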
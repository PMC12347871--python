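"""Univariate contingency statistics, group frequencies, co-localized
cluster detection, and region summaries.

Each feature's association with MRD status is a 2x2 table (carriers vs
non-carriers in the MRD-positive and MRD-negative groups) tested with a
two-sided Fisher exact test (point-probability convention: the two-sided p
sums hypergeometric point probabilities no larger than the observed
table's) and summarized by an odds ratio with the Haldane–Anscombe 0.5
correction when any cell is zero. Raw p-values are adjusted with
Benjamini–Hochberg by default.

Cluster detection reads co-localization off the top-ranked features: genes
sharing a canonical event on one chromosome are chained while consecutive
gene intervals are separated by at most ``max_gap`` bases; chains with
enough genes are reported as region clusters labeled by their spanned
cytobands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .encoding import GeneEventFeature, GeneEventMatrix, canonical_event, overlaps
from .errors import ValidationError
from .segments import AberrationSegment, GeneAnnotation, GenomicInterval

_ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


def contingency(
    matrix: GeneEventMatrix, labels, feature_id: str
) -> tuple[int, int, int, int]:
    """Carrier counts (a, b, c, d): MRD+ carriers, MRD+ non-carriers,
    MRD- carriers, MRD- non-carriers."""
    if not matrix.has_feature(feature_id):
        raise ValidationError(f"unknown feature {feature_id!r}")
    y = np.asarray(labels, dtype=bool)
    col = matrix.column(feature_id).astype(bool)
    a = int((col & y).sum())
    b = int((~col & y).sum())
    c = int((col & ~y).sum())
    d = int((~col & ~y).sum())
    return a, b, c, d


def _check_counts(a: int, b: int, c: int, d: int) -> None:
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError(f"counts must be non-negative integers, "
                                  f"got {(a, b, c, d)}")


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    _check_counts(a, b, c, d)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c); with any zero cell, Haldane–Anscombe: add 0.5 to all
    cells first, keeping the ratio finite and non-zero."""
    _check_counts(a, b, c, d)
    if min(a, b, c, d) == 0:
        a, b, c, d = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    return float((a * d) / (b * c))


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, mapped back to input order.

    ``method``: 'bh' (Benjamini–Hochberg step-up, default), 'bonferroni',
    or 'holm'. Adjusted values satisfy p <= q <= 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    try:
        sm_method = _ADJUST_METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown method {method!r}; choose from {sorted(_ADJUST_METHODS)}"
        ) from None
    q = multipletests(p, method=sm_method)[1]
    return np.minimum(np.maximum(q, p), 1.0)


@dataclass(frozen=True)
class ContingencyResult:
    """Per-feature 2x2 association with MRD status."""

    feature_id: str
    a: int  # MRD+ carriers
    b: int  # MRD+ non-carriers
    c: int  # MRD- carriers
    d: int  # MRD- non-carriers
    odds_ratio: float
    p_raw: float
    q_adj: float


def association_table(
    matrix: GeneEventMatrix,
    labels,
    feature_ids: Sequence[str] | None = None,
    method: str = "bh",
) -> pd.DataFrame:
    """Fisher/odds-ratio association for each feature, with adjusted p.

    Columns: feature_id, a, b, c, d, odds_ratio, p_raw, q_adj. The
    adjustment is computed over exactly the features tested here.
    """
    ids = list(feature_ids) if feature_ids is not None else matrix.feature_ids
    rows = []
    for fid in ids:
        a, b, c, d = contingency(matrix, labels, fid)
        rows.append((fid, a, b, c, d, odds_ratio(a, b, c, d),
                     fisher_exact(a, b, c, d)))
    table = pd.DataFrame(
        rows, columns=["feature_id", "a", "b", "c", "d", "odds_ratio",
                       "p_raw"],
    )
    table["q_adj"] = adjust_pvalues(table.p_raw.to_numpy(), method=method)
    return table


def frequency_table(
    matrix: GeneEventMatrix,
    labels,
    reference_matrix: GeneEventMatrix | None = None,
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Carrier fraction per group for each feature.

    Columns: freq_mrd_pos, freq_mrd_neg and, when a reference matrix is
    given, freq_reference (0 for features absent there). Indexed by
    feature id.
    """
    y = np.asarray(labels, dtype=bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValidationError("both MRD groups must be non-empty")
    if reference_matrix is not None and not reference_matrix.sample_ids:
        raise ValidationError("reference group is empty")
    ids = list(feature_ids) if feature_ids is not None else matrix.feature_ids
    rows = {}
    for fid in ids:
        col = matrix.column(fid).astype(bool)
        row = {
            "freq_mrd_pos": float(col[y].mean()),
            "freq_mrd_neg": float(col[~y].mean()),
        }
        if reference_matrix is not None:
            row["freq_reference"] = float(
                reference_matrix.column(fid).astype(bool).mean()
            )
        rows[fid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_id"
    return out


def region_frequency(
    feature_ids: Sequence[str],
    matrix: GeneEventMatrix,
    labels,
    reference_matrix: GeneEventMatrix | None = None,
) -> pd.Series:
    """Region-level frequency: the mean of member-gene carrier fractions
    per group (per-gene values come from :func:`frequency_table`)."""
    table = frequency_table(matrix, labels, reference_matrix,
                            feature_ids=feature_ids)
    return table.mean(axis=0)


@dataclass(frozen=True)
class RegionCluster:
    """Co-localized top features sharing one canonical event."""

    label: str  # cytoband range, e.g. "19q13.2-19q13.31"
    chrom: str
    start: int
    end: int
    canon_event: str
    feature_ids: tuple[str, ...]
    bands: tuple[str, ...]
    freq_mrd_pos: float | None = None
    freq_mrd_neg: float | None = None
    freq_reference: float | None = None


def detect_clusters(
    top_features: pd.DataFrame | Sequence[str],
    catalog: Sequence[GeneAnnotation],
    max_gap: int = 1_000_000,
    min_genes: int = 5,
) -> list[RegionCluster]:
    """Chain co-localized top features into region clusters.

    ``top_features`` is either a ranking table with a ``feature_id`` column
    or a plain sequence of feature ids. Features are grouped by canonical
    event and chromosome, ordered by gene start, and chained while the gap
    between consecutive gene intervals is at most ``max_gap`` bases; chains
    with at least ``min_genes`` genes are emitted, sorted by genomic
    position. Output is invariant to the order of the input features.
    """
    if isinstance(top_features, pd.DataFrame):
        ids = list(top_features["feature_id"])
    else:
        ids = list(top_features)
    genes = {g.symbol: g for g in catalog}
    by_group: dict[tuple[str, str], list[tuple[GeneAnnotation, str]]] = {}
    for fid in ids:
        feat = GeneEventFeature.from_id(fid)
        gene = genes.get(feat.symbol)
        if gene is None:
            raise ValidationError(
                f"feature {fid!r}: gene {feat.symbol!r} not in catalog"
            )
        key = (feat.canon_event, gene.interval.chrom)
        by_group.setdefault(key, []).append((gene, fid))

    clusters: list[RegionCluster] = []
    for (event, chrom), members in by_group.items():
        members.sort(key=lambda t: (t[0].interval.start, t[0].interval.end,
                                    t[0].symbol))
        chain: list[tuple[GeneAnnotation, str]] = []
        chain_end = None

        def flush():
            if len(chain) >= min_genes:
                bands = tuple(dict.fromkeys(g.band for g, _ in chain))
                label = (bands[0] if len(bands) == 1
                         else f"{bands[0]}-{bands[-1]}")
                clusters.append(
                    RegionCluster(
                        label=label,
                        chrom=chrom,
                        start=chain[0][0].interval.start,
                        end=max(g.interval.end for g, _ in chain),
                        canon_event=event,
                        feature_ids=tuple(fid for _, fid in chain),
                        bands=bands,
                    )
                )

        for gene, fid in members:
            if chain and gene.interval.start - chain_end - 1 > max_gap:
                flush()
                chain = []
                chain_end = None
            chain.append((gene, fid))
            chain_end = (gene.interval.end if chain_end is None
                         else max(chain_end, gene.interval.end))
        flush()
    clusters.sort(key=lambda c: (c.chrom, c.start, c.canon_event))
    return clusters


def annotate_cluster_frequencies(
    clusters: Iterable[RegionCluster],
    matrix: GeneEventMatrix,
    labels,
    reference_matrix: GeneEventMatrix | None = None,
) -> list[RegionCluster]:
    """Attach per-group region frequencies (mean over member genes)."""
    out = []
    for c in clusters:
        freqs = region_frequency(list(c.feature_ids), matrix, labels,
                                 reference_matrix)
        out.append(
            replace(
                c,
                freq_mrd_pos=float(freqs["freq_mrd_pos"]),
                freq_mrd_neg=float(freqs["freq_mrd_neg"]),
                freq_reference=(float(freqs["freq_reference"])
                                if "freq_reference" in freqs else None),
            )
        )
    return out


def region_summary(
    segments: Sequence[AberrationSegment],
    region: GenomicInterval,
    event_type: str,
    catalog: Sequence[GeneAnnotation],
    groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-group min/median/max of segment size, marker count and
    overlapped-gene count, over segments of the region's event type that
    overlap the region.

    ``groups`` maps a group name to its sample ids. A group with no
    qualifying segment raises :class:`ValidationError` naming the group.
    Returns a DataFrame indexed by (group, stat in min/median/max) with
    columns size_kb, marker_count, gene_count.
    """
    canon = canonical_event(event_type)
    qualifying = [
        s for s in segments
        if canonical_event(s.event_type) == canon
        and overlaps(s.interval, region)
    ]
    rows = []
    for group, sample_ids in groups.items():
        members = set(sample_ids)
        segs = [s for s in qualifying if s.sample_id in members]
        if not segs:
            raise ValidationError(
                f"group {group!r} has no {canon} segment overlapping "
                f"{region.chrom}:{region.start}-{region.end}"
            )
        sizes = np.array([s.size_kb for s in segs])
        markers = np.array([s.marker_count for s in segs])
        gene_counts = np.array([
            sum(overlaps(s.interval, g.interval) for g in catalog)
            for s in segs
        ])
        for stat, fn in (("min", np.min), ("median", np.median),
                         ("max", np.max)):
            rows.append((group, stat, float(fn(sizes)), float(fn(markers)),
                         float(fn(gene_counts))))
    out = pd.DataFrame(
        rows, columns=["group", "stat", "size_kb", "marker_count",
                       "gene_count"],
    ).set_index(["group", "stat"])
    return out
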
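"""Synthetic CMA cohorts with planted region-level aberration clusters.

The generator emulates the structure of an adult B-ALL biomarker study:
a labeled patient cohort (MRD-positive vs MRD-negative remission after
induction), a 3x sex/age-matched healthy reference pool, a gene catalog,
and per-sample aberration segments. Three region-level event clusters are
planted by default — a cnLOH cluster on a 19q13-like region (carrying a
PSG-family-like tiling of genes) and two mosaic-loss clusters on 7p22.3-
and 16q13-like regions — each carried independently per sample at its
group-specific frequency, on top of uniform background aberration noise.

Everything is deterministic given the configured seed: one seed fans out to
independent streams in a fixed draw order (catalog, patients, patient
segments, reference pool), so e.g. adding background genes never perturbs
cohort labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, FormatError, ValidationError
from .segments import (
    AberrationSegment,
    GeneAnnotation,
    GenomicInterval,
    QCThresholds,
)

#: Synthetic autosome lengths (bp), genome-build-like magnitudes.
GENOME: dict[str, int] = {
    f"chr{i}": length
    for i, length in zip(
        range(1, 23),
        [248_000_000, 242_000_000, 198_000_000, 190_000_000, 181_000_000,
         171_000_000, 159_000_000, 145_000_000, 138_000_000, 134_000_000,
         135_000_000, 133_000_000, 114_000_000, 107_000_000, 102_000_000,
         90_000_000, 83_000_000, 80_000_000, 59_000_000, 64_000_000,
         47_000_000, 51_000_000],
    )
}

SEXES = ("M", "F")
MRD_STATUSES = ("positive", "negative", "unknown")
COHORTS = ("patient", "reference")

SAMPLE_COLUMNS = ("sample_id", "sex", "age", "mrd_status", "cohort")


@dataclass(frozen=True)
class PatientRecord:
    """A study participant: patient (with MRD label) or healthy reference."""

    sample_id: str
    sex: str
    age: int
    mrd_status: str
    cohort: str

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.mrd_status not in MRD_STATUSES:
            raise ValidationError(f"bad mrd_status {self.mrd_status!r}")
        if self.cohort not in COHORTS:
            raise ValidationError(f"bad cohort {self.cohort!r}")
        if self.cohort == "reference" and self.mrd_status != "unknown":
            raise ValidationError(
                "reference records carry no MRD label (must be 'unknown')"
            )


@dataclass(frozen=True)
class PlantedCluster:
    """A region-level event planted at group-specific carrier frequencies."""

    region: GenomicInterval
    event_type: str
    freq_mrd_pos: float
    freq_mrd_neg: float
    freq_reference: float
    #: Gene symbols tiled across the region (>= 10 for a realistic cluster).
    gene_symbols: tuple[str, ...]
    #: Cytoband labels assigned to the tiled genes, first-to-last.
    bands: tuple[str, ...]

    def __post_init__(self):
        for name in ("freq_mrd_pos", "freq_mrd_neg", "freq_reference"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {f}")
        if not self.gene_symbols:
            raise ConfigError("planted cluster needs at least one gene symbol")


_PSG_LIKE = ("PSG10P", "PSG11", "PSG1", "PSG2", "PSG4", "PSG5", "PSG6",
             "PSG7", "PSG8", "PSG8-AS1", "PSG9", "ERF")
_7P_LIKE = ("MAFK", "MICALL2", "MIR339", "MIR4655", "PDGFA-DT", "PDGFA",
            "PRKAR1B-AS1", "ADAP1", "C7ORF50", "COX19", "CYP2W1")
_MT_LIKE = ("MT1A", "MT1B", "MT1DP", "MT1E", "MT1F", "MT1G", "MT1H",
            "MT1IP", "MT1JP", "MT1L", "MT1M", "MT1X", "MT2A", "MT3",
            "MT4", "NUP93-DT", "NUP93")


def default_planted_clusters(preset: str = "abstract") -> list[PlantedCluster]:
    """The three default clusters at the emulated cohort's group rates.

    ``preset`` selects how the 19q13-like cnLOH frequencies are specified:
    ``"abstract"`` uses the rounded headline rates (0.70 / 0.16 / 0.47),
    ``"table1"`` the raw carrier counts (13/17 and 3/18, reference 0.47).
    The two differ slightly (13/17 is 76%); both are exposed rather than
    reconciled. The mosaic-loss clusters use their carrier counts (6/17,
    1/18) and are absent from the reference pool in both presets.
    """
    if preset == "abstract":
        loh_freqs = (0.70, 0.16, 0.47)
    elif preset == "table1":
        loh_freqs = (13 / 17, 3 / 18, 0.47)
    else:
        raise ConfigError(f"unknown preset {preset!r}")
    return [
        PlantedCluster(
            region=GenomicInterval("chr19", 42_500_001, 44_000_000),
            event_type="cnLOH",
            freq_mrd_pos=loh_freqs[0],
            freq_mrd_neg=loh_freqs[1],
            freq_reference=loh_freqs[2],
            gene_symbols=_PSG_LIKE,
            bands=("19q13.2",) * 6 + ("19q13.31",) * 6,
        ),
        PlantedCluster(
            region=GenomicInterval("chr7", 100_001, 2_600_000),
            event_type="loss_mosaic",
            freq_mrd_pos=6 / 17,
            freq_mrd_neg=1 / 18,
            freq_reference=0.0,
            gene_symbols=_7P_LIKE,
            bands=("7p22.3",) * len(_7P_LIKE),
        ),
        PlantedCluster(
            region=GenomicInterval("chr16", 56_600_001, 57_600_000),
            event_type="loss_mosaic",
            freq_mrd_pos=6 / 17,
            freq_mrd_neg=1 / 18,
            freq_reference=0.0,
            gene_symbols=_MT_LIKE,
            bands=("16q13",) * len(_MT_LIKE),
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort structure and noise levels for the synthetic study.

    Defaults reproduce the study layout: 17 MRD-positive and 18 MRD-negative
    patients, a 3x reference pool (105 records), planted clusters at the
    default group rates, 1000 background genes and an expected 30
    background aberrations per sample.
    """

    n_mrd_pos: int = 17
    n_mrd_neg: int = 18
    reference_multiplier: int = 3
    planted_clusters: tuple[PlantedCluster, ...] = field(
        default_factory=lambda: tuple(default_planted_clusters())
    )
    background_rate: float = 30.0
    n_background_genes: int = 1000
    age_range: tuple[int, int] = (18, 58)
    male_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self):
        if self.n_mrd_pos + self.n_mrd_neg <= 0:
            raise ConfigError("cohort must contain at least one patient")
        if self.reference_multiplier < 1:
            raise ConfigError("reference_multiplier must be >= 1")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigError(f"bad age_range {self.age_range}")
        regions = sorted(
            (c.region for c in self.planted_clusters),
            key=lambda r: (r.chrom, r.start),
        )
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ConfigError(
                    f"planted regions overlap: {a.chrom}:{a.start}-{a.end} "
                    f"and {b.chrom}:{b.start}-{b.end}"
                )


# Fixed draw order: one sub-stream per generation stage.
_STREAMS = ("catalog", "patients", "patient_segments", "reference_pool")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _band_label(chrom: str, pos: int) -> str:
    """Synthetic cytoband for background genes: arm by position, band index
    by tenth of arm length."""
    length = GENOME[chrom]
    centromere = 0.4 * length
    if pos <= centromere:
        arm, frac = "p", 1.0 - pos / centromere
    else:
        arm, frac = "q", (pos - centromere) / (length - centromere)
    return f"{chrom.removeprefix('chr')}{arm}{min(int(frac * 10) + 11, 20)}"


def generate_gene_catalog(config: SimulationConfig) -> list[GeneAnnotation]:
    """Tile >= 10 genes inside each planted region plus background genes
    genome-wide (chromosomes weighted by length). Deterministic given seed."""
    rng = _rng(config, "catalog")
    genes: list[GeneAnnotation] = []
    for cluster in config.planted_clusters:
        r = cluster.region
        n = len(cluster.gene_symbols)
        # evenly spaced gene bodies covering ~60% of the region
        slot = r.size_bp // n
        width = max(int(0.6 * slot), 1000)
        for k, symbol in enumerate(cluster.gene_symbols):
            start = r.start + k * slot + (slot - width) // 2
            band = cluster.bands[min(k, len(cluster.bands) - 1)]
            genes.append(
                GeneAnnotation(symbol, GenomicInterval(r.chrom, start,
                                                       start + width - 1),
                               band)
            )
    chroms = list(GENOME)
    weights = np.array([GENOME[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    planted = {(g.interval.chrom, g.interval.start) for g in genes}
    for k in range(config.n_background_genes):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        width = int(rng.integers(5_000, 200_000))
        start = int(rng.integers(1, GENOME[chrom] - width))
        if (chrom, start) in planted:
            start += width  # vanishingly rare; keep symbols unique anyway
        genes.append(
            GeneAnnotation(f"BG{k:05d}", GenomicInterval(chrom, start,
                                                         start + width - 1),
                           _band_label(chrom, start))
        )
    return genes


def _planted_segment(
    rng: np.random.Generator, sample_id: str, cluster: PlantedCluster
) -> AberrationSegment:
    """Emit one planted event spanning the region, with endpoint jitter and
    QC-passing metrics. Losses are subclonal (mosaic fraction in [0.2, 0.8])."""
    r = cluster.region
    pad = int(0.10 * r.size_bp)
    start = max(1, r.start - int(rng.integers(0, pad + 1)))
    end = min(GENOME.get(r.chrom, r.end + pad),
              r.end + int(rng.integers(0, pad + 1)))
    interval = GenomicInterval(r.chrom, start, end)
    # SNP-marker density ~0.14/kb, the scale seen on CMA platforms
    markers = max(60, int(interval.size_kb * rng.normal(0.14, 0.02)))
    if cluster.event_type == "cnLOH":
        return AberrationSegment(sample_id, interval, "cnLOH", markers)
    if cluster.event_type == "gain":
        return AberrationSegment(sample_id, interval, "gain", markers,
                                 mean_log2ratio=float(rng.uniform(0.3, 0.6)))
    return AberrationSegment(
        sample_id, interval, cluster.event_type, markers,
        mean_log2ratio=float(-rng.uniform(0.3, 0.6)),
        mosaic_fraction=float(rng.uniform(0.2, 0.8)),
    )


def _background_segments(
    rng: np.random.Generator, sample_id: str, rate: float,
    qc: QCThresholds,
) -> list[AberrationSegment]:
    """Poisson(rate) background aberrations, log-uniform 100 kb – 10 Mb,
    placed uniformly; QC-passing by construction."""
    out = []
    chroms = list(GENOME)
    weights = np.array([GENOME[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(rng.poisson(rate)):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        size = int(10 ** rng.uniform(5, 7))  # 100 kb .. 10 Mb
        size = min(size, GENOME[chrom] - 1)
        start = int(rng.integers(1, GENOME[chrom] - size))
        interval = GenomicInterval(chrom, start, start + size - 1)
        event = ("gain", "loss", "loss_mosaic", "cnLOH")[rng.integers(4)]
        density = rng.normal(0.14, 0.02)
        if event == "cnLOH":
            markers = max(qc.min_markers_loh, int(interval.size_kb * density))
            out.append(AberrationSegment(sample_id, interval, event, markers))
            continue
        if event == "gain":
            markers = max(qc.min_markers_gain, int(interval.size_kb * density))
            log2 = float(rng.uniform(0.3, 0.8))
            mosaic = None
        else:
            markers = max(qc.min_markers_loss, int(interval.size_kb * density))
            log2 = float(-rng.uniform(0.3, 0.8))
            mosaic = (float(rng.uniform(0.2, 0.9))
                      if event == "loss_mosaic" else None)
        out.append(AberrationSegment(sample_id, interval, event, markers,
                                     mean_log2ratio=log2,
                                     mosaic_fraction=mosaic))
    return out


def _sample_segments(
    rng: np.random.Generator,
    record: PatientRecord,
    config: SimulationConfig,
    qc: QCThresholds,
) -> list[AberrationSegment]:
    freq_field = {
        "positive": "freq_mrd_pos",
        "negative": "freq_mrd_neg",
        "unknown": "freq_reference",
    }[record.mrd_status]
    segs = []
    for cluster in config.planted_clusters:
        if rng.random() < getattr(cluster, freq_field):
            segs.append(_planted_segment(rng, record.sample_id, cluster))
    segs.extend(_background_segments(rng, record.sample_id,
                                     config.background_rate, qc))
    return segs


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], list[AberrationSegment]]:
    """Generate the labeled patient cohort and its aberration segments.

    Each patient carries each planted event independently at the frequency
    of their MRD group; background segments follow a per-sample Poisson
    count. All emitted segments pass the default QC filter by construction.
    """
    qc = QCThresholds()
    rng_p = _rng(config, "patients")
    n = config.n_mrd_pos + config.n_mrd_neg
    statuses = (["positive"] * config.n_mrd_pos
                + ["negative"] * config.n_mrd_neg)
    patients = []
    lo, hi = config.age_range
    for i, status in enumerate(statuses):
        patients.append(
            PatientRecord(
                sample_id=f"P{i + 1:03d}",
                sex="M" if rng_p.random() < config.male_fraction else "F",
                age=int(rng_p.integers(lo, hi + 1)),
                mrd_status=status,
                cohort="patient",
            )
        )
    rng_s = _rng(config, "patient_segments")
    segments: list[AberrationSegment] = []
    for rec in patients:
        segments.extend(_sample_segments(rng_s, rec, config, qc))
    return patients, segments


def generate_reference_pool(
    config: SimulationConfig, patients: Sequence[PatientRecord]
) -> tuple[list[PatientRecord], list[AberrationSegment]]:
    """Generate the healthy reference pool: ``reference_multiplier`` records
    per patient, same sex, age jittered by at most 2 years (clipped to the
    configured range) so exact-sex nearest-age triple matching is feasible.
    Planted events are emitted at each cluster's reference frequency.
    """
    if not patients:
        raise ConfigError("patients must be non-empty")
    qc = QCThresholds()
    rng = _rng(config, "reference_pool")
    lo, hi = config.age_range
    pool: list[PatientRecord] = []
    segments: list[AberrationSegment] = []
    k = 0
    for patient in patients:
        for _ in range(config.reference_multiplier):
            k += 1
            age = int(np.clip(patient.age + rng.integers(-2, 3), lo, hi))
            rec = PatientRecord(
                sample_id=f"R{k:03d}",
                sex=patient.sex,
                age=age,
                mrd_status="unknown",
                cohort="reference",
            )
            pool.append(rec)
            segments.extend(_sample_segments(rng, rec, config, qc))
    return pool, segments


@dataclass
class SimulatedStudy:
    """All artifacts of one synthetic study run."""

    catalog: list[GeneAnnotation]
    patients: list[PatientRecord]
    patient_segments: list[AberrationSegment]
    references: list[PatientRecord]
    reference_segments: list[AberrationSegment]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all generation stages in the documented draw order."""
    catalog = generate_gene_catalog(config)
    patients, patient_segments = generate_cohort(config)
    references, reference_segments = generate_reference_pool(config, patients)
    return SimulatedStudy(catalog, patients, patient_segments,
                          references, reference_segments)


# -- samples-table interchange --------------------------------------------


def write_samples(records: Iterable[PatientRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.sex}\t{r.age}\t{r.mrd_status}\t"
                     f"{r.cohort}\n")


def read_samples(path: str | Path) -> list[PatientRecord]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in SAMPLE_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in SAMPLE_COLUMNS}
        records = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            try:
                records.append(
                    PatientRecord(
                        sample_id=parts[idx["sample_id"]],
                        sex=parts[idx["sex"]],
                        age=int(parts[idx["age"]]),
                        mrd_status=parts[idx["mrd_status"]],
                        cohort=parts[idx["cohort"]],
                    )
                )
            except (ValueError, ValidationError, IndexError) as exc:
                raise FormatError(str(exc), line=lineno) from None
    return records


def mrd_labels(
    records: Sequence[PatientRecord], sample_ids: Sequence[str]
) -> np.ndarray:
    """Boolean MRD labels (True = positive) aligned to ``sample_ids``."""
    status = {r.sample_id: r.mrd_status for r in records}
    out = []
    for sid in sample_ids:
        st = status.get(sid)
        if st not in ("positive", "negative"):
            raise ValidationError(
                f"sample {sid!r} has no binary MRD label (status={st!r})"
            )
        out.append(st == "positive")
    return np.asarray(out, dtype=bool)
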
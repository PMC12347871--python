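"""Triple sex/age-matched reference construction and patient-vs-reference
frequency comparison.

Each patient is assigned exactly three references of the same sex, drawn
without replacement from the healthy pool, minimizing absolute age
difference. The default policy is deterministic greedy assignment in
sorted patient order (nearest ages first, ties by reference id); an
optional globally optimal mode solves the assignment problem over all
patient slots at once. Matching uses demographics only — never aberration
data — so the comparison cannot leak outcome information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .encoding import GeneEventMatrix
from .errors import MatchingError, ValidationError
from .simulate import PatientRecord
from .stats import fisher_exact

N_PER_PATIENT = 3


@dataclass(frozen=True)
class MatchedReference:
    """Patient -> three same-sex references, with mean |age difference|."""

    assignments: Mapping[str, tuple[str, str, str]]
    quality: float  # mean absolute age difference in years

    def reference_ids(self) -> list[str]:
        return [rid for refs in self.assignments.values() for rid in refs]


def _feasibility_check(patients: Sequence[PatientRecord],
                       pool: Sequence[PatientRecord]) -> None:
    if len(pool) < N_PER_PATIENT * len(patients):
        raise MatchingError(
            f"pool of {len(pool)} is smaller than "
            f"{N_PER_PATIENT} x {len(patients)} patients"
        )
    for sex in ("M", "F"):
        need = N_PER_PATIENT * sum(p.sex == sex for p in patients)
        have = sum(r.sex == sex for r in pool)
        if have < need:
            first = next(p for p in sorted(patients, key=lambda p: p.sample_id)
                         if p.sex == sex)
            raise MatchingError(
                f"pool has {have} sex-{sex} members but {need} are needed; "
                f"patient {first.sample_id} cannot be matched"
            )


def _greedy(patients: Sequence[PatientRecord],
            pool: Sequence[PatientRecord]) -> dict[str, tuple[str, ...]]:
    available = {r.sample_id: r for r in pool}
    assignments: dict[str, tuple[str, ...]] = {}
    for patient in sorted(patients, key=lambda p: p.sample_id):
        candidates = sorted(
            (r for r in available.values() if r.sex == patient.sex),
            key=lambda r: (abs(r.age - patient.age), r.sample_id),
        )
        if len(candidates) < N_PER_PATIENT:
            raise MatchingError(
                f"pool exhausted: patient {patient.sample_id} has only "
                f"{len(candidates)} same-sex candidates left"
            )
        chosen = candidates[:N_PER_PATIENT]
        assignments[patient.sample_id] = tuple(r.sample_id for r in chosen)
        for r in chosen:
            del available[r.sample_id]
    return assignments


def _optimal(patients: Sequence[PatientRecord],
             pool: Sequence[PatientRecord]) -> dict[str, tuple[str, ...]]:
    """Globally minimal total |age difference| via the assignment problem:
    each patient contributes three slots; sex mismatches carry a
    prohibitive cost and are rejected if ever selected."""
    patients = sorted(patients, key=lambda p: p.sample_id)
    pool = sorted(pool, key=lambda r: r.sample_id)
    big = 10_000.0
    cost = np.full((N_PER_PATIENT * len(patients), len(pool)), big)
    for i, p in enumerate(patients):
        for j, r in enumerate(pool):
            if r.sex == p.sex:
                c = abs(r.age - p.age)
                for slot in range(N_PER_PATIENT):
                    cost[N_PER_PATIENT * i + slot, j] = c
    rows, cols = linear_sum_assignment(cost)
    if cost[rows, cols].max() >= big:
        raise MatchingError("no sex-feasible global assignment exists")
    assignments: dict[str, tuple[str, ...]] = {}
    for i, p in enumerate(patients):
        slots = [cols[np.where(rows == N_PER_PATIENT * i + s)[0][0]]
                 for s in range(N_PER_PATIENT)]
        assignments[p.sample_id] = tuple(
            sorted(pool[j].sample_id for j in slots)
        )
    return assignments


def match_triple(
    patients: Sequence[PatientRecord],
    pool: Sequence[PatientRecord],
    method: str = "greedy",
) -> MatchedReference:
    """Assign three same-sex, nearest-age references to every patient.

    ``method`` is ``"greedy"`` (deterministic, patients in sorted-id order,
    ties by reference id) or ``"optimal"`` (global assignment-problem
    solution minimizing total age difference). References are used without
    replacement. Raises :class:`MatchingError` when the pool is too small
    or a sex is exhausted.
    """
    if not patients:
        raise ValidationError("patients must be non-empty")
    _feasibility_check(patients, pool)
    if method == "greedy":
        assignments = _greedy(patients, pool)
    elif method == "optimal":
        assignments = _optimal(patients, pool)
    else:
        raise ValidationError(f"unknown method {method!r}")
    age = {r.sample_id: r.age for r in list(patients) + list(pool)}
    diffs = [
        abs(age[rid] - age[pid])
        for pid, refs in assignments.items()
        for rid in refs
    ]
    return MatchedReference(assignments=assignments,
                            quality=float(np.mean(diffs)))


def write_assignments(matched: MatchedReference, patients, pool,
                      path) -> None:
    """Assignment TSV: patient_id, ref_id_1..3, age_diff_1..3."""
    age = {r.sample_id: r.age for r in list(patients) + list(pool)}
    with open(path, "w") as fh:
        fh.write("patient_id\tref_id_1\tref_id_2\tref_id_3\t"
                 "age_diff_1\tage_diff_2\tage_diff_3\n")
        for pid in sorted(matched.assignments):
            refs = matched.assignments[pid]
            diffs = [abs(age[r] - age[pid]) for r in refs]
            fh.write(pid + "\t" + "\t".join(refs) + "\t"
                     + "\t".join(str(d) for d in diffs) + "\n")


def compare_with_reference(
    patient_matrix: GeneEventMatrix,
    reference_matrix: GeneEventMatrix,
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Carrier frequency in patients vs references with a two-sided Fisher
    exact p per feature.

    Feature dictionaries are merged by id; a feature absent from one matrix
    counts zero carriers there. Columns: patient_freq, reference_freq, p;
    indexed by feature id.
    """
    n_pat = len(patient_matrix.sample_ids)
    n_ref = len(reference_matrix.sample_ids)
    if n_pat == 0 or n_ref == 0:
        raise ValidationError("both cohorts must be non-empty")
    if feature_ids is None:
        feature_ids = sorted(
            set(patient_matrix.feature_ids) | set(reference_matrix.feature_ids)
        )
    rows = {}
    for fid in feature_ids:
        a = int(patient_matrix.column(fid).sum())
        c = int(reference_matrix.column(fid).sum())
        rows[fid] = {
            "patient_freq": a / n_pat,
            "reference_freq": c / n_ref,
            "p": fisher_exact(a, n_pat - a, c, n_ref - c),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_id"
    return out
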
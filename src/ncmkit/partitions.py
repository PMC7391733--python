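"""Per-country, per-age-bin neutral-model fits and comparison of classification sets.

Samples are grouped into three-month age bins within each country, the neutral
model is refit with the regional pool estimated from each partition's own
samples, and the migration rate m is reported with a subject-level bootstrap
confidence interval. Classification sets (which taxa sit above / within / below
the prediction band) are compared across partitions with Jaccard distances and
summarised by classical multidimensional scaling (principal coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Z95, NCMFitResult, fit_ncm, wilson_interval
from .tables import Cohort, build_source_pool, occurrence_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "PartitionFit",
    "PartitionSkip",
    "make_age_partitions",
    "fit_partition",
    "fit_partitions",
    "classification_jaccard",
    "classical_mds",
    "partition_summary_frame",
]

DEFAULT_BIN_EDGES = (1, 4, 7, 10, 13)


@dataclass(frozen=True)
class Partition:
    """Samples of one country whose age in whole months falls in [age_lo, age_hi)."""

    country: str
    age_lo: float
    age_hi: float
    sample_ids: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"{self.country}:{int(self.age_lo)}-{int(self.age_hi) - 1}mo"


@dataclass(frozen=True)
class PartitionFit:
    partition: Partition
    fit: NCMFitResult
    m_ci: tuple[float, float]
    m_ci_wilson: tuple[float, float]
    m_boot: np.ndarray
    class_sets: dict[str, set[str]]


@dataclass(frozen=True)
class PartitionSkip:
    partition: Partition
    reason: str


def make_age_partitions(cohort: Cohort, bin_edges=DEFAULT_BIN_EDGES) -> list[Partition]:
    """Assign samples to (country, age-bin) partitions.

    Bin membership uses the age in whole months (floor of ``age_months``) and
    half-open intervals ``[lo, hi)``. Samples outside every bin are excluded
    (their count is logged); empty partitions are retained with a warning so
    the caller sees the full design.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing with at least two values")
    countries = sorted({r.country for r in cohort.records})
    assigned: dict[tuple[str, int], list[str]] = {
        (c, k): [] for c in countries for k in range(len(edges) - 1)
    }
    n_excluded = 0
    for rec in cohort.records_aligned():
        whole = np.floor(rec.age_months)
        k = np.searchsorted(edges, whole, side="right") - 1
        if k < 0 or k >= len(edges) - 1:
            n_excluded += 1
            continue
        assigned[(rec.country, int(k))].append(rec.sample_id)
    if n_excluded:
        logger.info("age partitioning: %d sample(s) outside all bins excluded", n_excluded)
    partitions = []
    for c in countries:
        for k in range(len(edges) - 1):
            ids = assigned[(c, k)]
            part = Partition(c, float(edges[k]), float(edges[k + 1]), tuple(ids))
            if not ids:
                logger.warning("partition %s is empty", part.label)
            partitions.append(part)
    return partitions


def _restrict(cohort: Cohort, sample_ids) -> Cohort:
    by_id = cohort._by_id
    table = cohort.table.select_samples(list(sample_ids))
    return Cohort(table, tuple(by_id[s] for s in sample_ids))


def fit_partition(
    cohort: Cohort,
    partition: Partition,
    n_boot: int = 200,
    seed: int = 0,
    confidence_z: float = Z95,
    pooling_rule: str = "pooled_counts",
    N: float | None = None,
    d: float | None = None,
    detection: str = "threshold",
    min_reads_detect: int = 1,
    min_samples: int = 5,
    ci_level: float = 0.95,
) -> PartitionFit | PartitionSkip:
    """Fit the neutral model within one partition.

    The source pool, N (mean read depth) and d are estimated from the
    partition's own samples. The primary CI on m is a percentile bootstrap over
    subject-level resamples: subjects drawn with replacement, then one sample
    per drawn subject. A Wilson interval treating m as a proportion with
    n = partition sample count is reported alongside for compatibility; Wilson
    intervals are defined for proportions, so this is a labelled approximation,
    not the primary interval.
    """
    if len(partition.sample_ids) < min_samples:
        return PartitionSkip(
            partition,
            f"only {len(partition.sample_ids)} sample(s); need >= {min_samples}",
        )
    sub = _restrict(cohort, partition.sample_ids)

    def _fit(c: Cohort) -> NCMFitResult:
        pool = build_source_pool(c, pooling_rule)
        freq = occurrence_frequency(c, min_reads_detect)
        depths = c.table.depths()
        N_i = float(N) if N is not None else float(depths.mean())
        return fit_ncm(
            pool,
            freq,
            N=N_i,
            d=d,
            confidence_z=confidence_z,
            n_obs=c.n_samples,
            detection=detection,
            depth=int(round(depths.mean())) if detection == "reads" else None,
            min_reads_detect=min_reads_detect,
        )

    try:
        fit = _fit(sub)
    except ValueError as exc:
        return PartitionSkip(partition, str(exc))

    subjects = sub.subjects()
    subject_ids = list(subjects)
    m_boot = []
    children = np.random.SeedSequence(seed).spawn(n_boot)
    for child in children:
        rng = np.random.default_rng(child)
        drawn = rng.choice(len(subject_ids), size=len(subject_ids), replace=True)
        chosen = []
        for k, si in enumerate(drawn):
            samples = subjects[subject_ids[si]]
            sid = samples[int(rng.integers(len(samples)))]
            # subject drawn twice contributes twice; disambiguate column ids
            chosen.append((sid, k))
        # build a resampled cohort allowing repeated samples via column copies
        base = sub.table
        cols = [base.sample_index(sid) for sid, _ in chosen]
        ids = [f"{sid}#{k}" for sid, k in chosen]
        from .tables import AbundanceTable, SampleRecord

        table = AbundanceTable(base.taxon_ids, tuple(ids), base.counts[:, cols])
        by_id = sub._by_id
        records = []
        for (sid, k), new_id in zip(chosen, ids):
            r = by_id[sid]
            records.append(
                SampleRecord(
                    sample_id=new_id,
                    subject_id=f"{r.subject_id}#{k}",
                    role=r.role,
                    body_site=r.body_site,
                    age_months=r.age_months,
                    country=r.country,
                    dyad_id=r.dyad_id,
                    village=r.village,
                    village_type=r.village_type,
                )
            )
        try:
            m_boot.append(_fit(Cohort(table, tuple(records))).params.m)
        except ValueError:
            continue
    m_boot = np.asarray(m_boot)
    alpha = 1.0 - ci_level
    if len(m_boot):
        m_ci = (
            float(np.quantile(m_boot, alpha / 2)),
            float(np.quantile(m_boot, 1 - alpha / 2)),
        )
    else:
        m_ci = (fit.params.m, fit.params.m)
    m_ci_wilson = wilson_interval(min(max(fit.params.m, 0.0), 1.0), sub.n_samples, confidence_z)
    return PartitionFit(
        partition=partition,
        fit=fit,
        m_ci=m_ci,
        m_ci_wilson=(float(m_ci_wilson[0]), float(m_ci_wilson[1])),
        m_boot=m_boot,
        class_sets=fit.classification_sets(),
    )


def fit_partitions(cohort: Cohort, partitions, **kwargs) -> list[PartitionFit | PartitionSkip]:
    return [fit_partition(cohort, part, **kwargs) for part in partitions]


def classification_jaccard(
    fits: list[PartitionFit], labels=("above", "within", "below")
) -> tuple[list[tuple[str, str, str]], np.ndarray]:
    """Jaccard distance matrix over (country, age-bin, class-label) taxon sets.

    Distance is ``1 - |A ∩ B| / |A ∪ B|``; two empty sets get distance 0 (with
    a warning), matching the convention that nothing differs between them.
    """
    keys: list[tuple[str, str, str]] = []
    sets: list[set[str]] = []
    for f in fits:
        for lab in labels:
            keys.append((f.partition.country, f.partition.label, lab))
            sets.append(f.class_sets.get(lab, set()))
    if sum(1 for s in sets if s) < 2:
        raise ValueError("need at least two nonempty classification sets")
    n = len(sets)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            if union == 0:
                logger.warning(
                    "both classification sets empty (%s vs %s); distance set to 0",
                    keys[i],
                    keys[j],
                )
                dist = 0.0
            else:
                dist = 1.0 - len(sets[i] & sets[j]) / union
            D[i, j] = D[j, i] = dist
    return keys, D


def classical_mds(distances: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling / principal coordinates.

    Double-centres the squared distance matrix and eigendecomposes it.
    Returns coordinates for the first ``k`` axes with positive eigenvalues
    (axes with nonpositive eigenvalues are dropped) and the full eigenvalue
    spectrum in descending order. Raises on asymmetric input.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = min(k, int(np.sum(eigvals > 1e-12)))
    coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep])
    return coords, eigvals


def partition_summary_frame(results) -> pd.DataFrame:
    """Tabulate partition fits (skipped partitions carry NaNs and a reason)."""
    rows = []
    for r in results:
        if isinstance(r, PartitionSkip):
            rows.append(
                {
                    "country": r.partition.country,
                    "age_lo": r.partition.age_lo,
                    "age_hi": r.partition.age_hi,
                    "n_samples": len(r.partition.sample_ids),
                    "skipped": r.reason,
                }
            )
            continue
        n_fit = r.fit.n_taxa_fit
        sets = r.class_sets
        rows.append(
            {
                "country": r.partition.country,
                "age_lo": r.partition.age_lo,
                "age_hi": r.partition.age_hi,
                "n_samples": len(r.partition.sample_ids),
                "n_taxa": n_fit,
                "m": r.fit.params.m,
                "m_ci_lower": r.m_ci[0],
                "m_ci_upper": r.m_ci[1],
                "m_wilson_lower": r.m_ci_wilson[0],
                "m_wilson_upper": r.m_ci_wilson[1],
                "rmse": r.fit.rmse,
                "frac_above": len(sets["above"]) / n_fit,
                "frac_within": len(sets["within"]) / n_fit,
                "frac_below": len(sets["below"]) / n_fit,
                "skipped": "",
            }
        )
    return pd.DataFrame(rows)
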
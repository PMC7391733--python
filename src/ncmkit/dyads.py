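"""Mother-infant dyad sharing statistics.

For each infant sample, every taxon the infant carries is attributed to
potential sources: the mother's samples at the same body site, the mother's
samples at the other body site, and same-site samples from other adults living
in the infant's village. "Shared within a dyad" means present in the infant
sample and in at least one of the mother's same-site samples (the mother's
time points are aggregated; per-time-point matching is available via
``aggregate_mother=False``). Additional summaries contrast the relative
abundance of shared vs non-shared taxa, relate per-taxon dyad sharing rates to
infant prevalence stratified by maternal abundance, and compare taxon overlap
between mothers within vs between villages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import Cohort, SampleRecord

__all__ = [
    "DyadSharingRecord",
    "infant_taxon_sources",
    "all_infant_sources",
    "shared_abundance_contrast",
    "sharing_rate_by_prevalence",
    "mother_pair_sharing",
]

ABUNDANCE_BINS = ("gt_0.1pct", "0.01_to_0.1pct", "le_0.01pct")
DEFAULT_AGE_WINDOWS = ((0.0, 6.0), (6.0, 12.0), (12.0, 18.0))


@dataclass(frozen=True)
class DyadSharingRecord:
    """Source attribution of the taxa present in one infant sample.

    ``fraction_mother_same_site`` / ``fraction_mother_other_site`` /
    ``fraction_village_adults_only`` are fractions of the infant's present taxa
    flagged per (non-exclusive) source; a same-site fraction of ``None`` means
    the mother has no sample at that site. The exclusive decomposition
    mother-any-site / village-adults-only / unobserved sums to 1.
    """

    infant_sample_id: str
    dyad_id: str
    body_site: str
    age_months: float
    fraction_mother_same_site: float | None
    fraction_mother_other_site: float | None
    fraction_village_adults_only: float
    fraction_mother_any: float
    fraction_unobserved: float
    n_infant_taxa: int


def _present_matrix(cohort: Cohort, min_reads: int) -> np.ndarray:
    return cohort.table.counts >= min_reads


def _sample_cols(cohort: Cohort, records) -> list[int]:
    return [cohort.table.sample_index(r.sample_id) for r in records]


def _mother_records(cohort: Cohort, dyad_id: str) -> list[SampleRecord]:
    return [r for r in cohort.records if r.dyad_id == dyad_id and r.role == "mother"]


def infant_taxon_sources(
    cohort: Cohort, infant_sample_id: str, min_reads: int = 1
) -> DyadSharingRecord:
    """Attribute one infant sample's taxa to maternal and village sources."""
    rec = cohort.record(infant_sample_id)
    if rec.role != "infant":
        raise ValueError(f"sample {infant_sample_id!r} is not an infant sample")
    if rec.dyad_id is None:
        raise ValueError(f"sample {infant_sample_id!r} has no dyad_id")
    mothers = _mother_records(cohort, rec.dyad_id)
    if not mothers:
        raise ValueError(f"dyad {rec.dyad_id!r} has no maternal samples in this cohort")

    present = _present_matrix(cohort, min_reads)
    infant = present[:, cohort.table.sample_index(infant_sample_id)]
    n_taxa = int(infant.sum())
    if n_taxa == 0:
        raise ValueError(
            f"sample {infant_sample_id!r} has no taxon at >= {min_reads} read(s)"
        )

    def union_over(records) -> np.ndarray:
        if not records:
            return np.zeros(present.shape[0], dtype=bool)
        return present[:, _sample_cols(cohort, records)].any(axis=1)

    mother_same = [m for m in mothers if m.body_site == rec.body_site]
    mother_other = [m for m in mothers if m.body_site != rec.body_site]
    mother_subjects = {m.subject_id for m in mothers}
    village_adults = [
        r
        for r in cohort.records
        if r.is_adult
        and r.body_site == rec.body_site
        and r.village is not None
        and r.village == rec.village
        and r.subject_id not in mother_subjects
    ]

    in_mother_same = union_over(mother_same)
    in_mother_other = union_over(mother_other)
    in_village = union_over(village_adults)
    in_mother_any = in_mother_same | in_mother_other

    frac = lambda flags: float((infant & flags).sum()) / n_taxa
    mother_any = frac(in_mother_any)
    village_only = frac(in_village & ~in_mother_any)
    unobserved = frac(~in_mother_any & ~in_village)
    return DyadSharingRecord(
        infant_sample_id=infant_sample_id,
        dyad_id=rec.dyad_id,
        body_site=rec.body_site,
        age_months=rec.age_months,
        fraction_mother_same_site=frac(in_mother_same) if mother_same else None,
        fraction_mother_other_site=frac(in_mother_other) if mother_other else None,
        fraction_village_adults_only=village_only,
        fraction_mother_any=mother_any,
        fraction_unobserved=unobserved,
        n_infant_taxa=n_taxa,
    )


def all_infant_sources(
    cohort: Cohort, body_site: str | None = None, min_reads: int = 1
) -> pd.DataFrame:
    """Source-attribution records for every resolvable infant sample."""
    rows = []
    for rec in cohort.records_aligned():
        if rec.role != "infant" or rec.dyad_id is None:
            continue
        if body_site is not None and rec.body_site != body_site:
            continue
        if not _mother_records(cohort, rec.dyad_id):
            continue
        r = infant_taxon_sources(cohort, rec.sample_id, min_reads)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)


def _mother_union_same_site(
    cohort: Cohort, present: np.ndarray, dyad_id: str, body_site: str
) -> np.ndarray | None:
    same = [m for m in _mother_records(cohort, dyad_id) if m.body_site == body_site]
    if not same:
        return None
    return present[:, _sample_cols(cohort, same)].any(axis=1)


def shared_abundance_contrast(
    cohort: Cohort,
    body_site: str,
    age_windows=DEFAULT_AGE_WINDOWS,
    min_reads: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean relative abundance of dyad-shared vs non-shared taxa, per sample.

    "Shared" taxa are present in the infant sample and in >= 1 of the mother's
    same-site samples. The infant side averages abundances in the infant
    sample over shared vs infant-only taxa; the mother side averages, across
    her same-site samples, the abundances of shared vs mother-only taxa.
    Two-sided Wilcoxon rank-sum tests compare shared vs non-shared means across
    samples within each age window, separately per side. Degenerate groups
    (e.g. every taxon shared) yield NaN means and are dropped from the tests;
    dyads without same-site maternal samples are skipped and counted.
    """
    present = _present_matrix(cohort, min_reads)
    props = cohort.table.proportions()
    rows = []
    n_skipped = 0
    for rec in cohort.records_aligned():
        if rec.role != "infant" or rec.body_site != body_site or rec.dyad_id is None:
            continue
        mother_union = _mother_union_same_site(cohort, present, rec.dyad_id, body_site)
        if mother_union is None:
            n_skipped += 1
            continue
        j = cohort.table.sample_index(rec.sample_id)
        infant = present[:, j]
        shared = infant & mother_union
        infant_only = infant & ~mother_union
        mother_only = mother_union & ~infant
        mother_cols = _sample_cols(
            cohort,
            [m for m in _mother_records(cohort, rec.dyad_id) if m.body_site == body_site],
        )
        mother_props = props[:, mother_cols].mean(axis=1)

        def mean_or_nan(values: np.ndarray, mask: np.ndarray) -> float:
            return float(values[mask].mean()) if mask.any() else float("nan")

        rows.append(
            {
                "infant_sample_id": rec.sample_id,
                "dyad_id": rec.dyad_id,
                "age_months": rec.age_months,
                "n_shared": int(shared.sum()),
                "n_infant_only": int(infant_only.sum()),
                "infant_shared_mean": mean_or_nan(props[:, j], shared),
                "infant_nonshared_mean": mean_or_nan(props[:, j], infant_only),
                "mother_shared_mean": mean_or_nan(mother_props, shared),
                "mother_nonshared_mean": mean_or_nan(mother_props, mother_only),
            }
        )
    if not rows:
        raise ValueError(f"no complete dyads with infant {body_site} samples")
    samples = pd.DataFrame(rows)
    samples.attrs["n_skipped_dyad_samples"] = n_skipped

    tests = []
    for lo, hi in age_windows:
        window = samples[(samples.age_months >= lo) & (samples.age_months < hi)]
        for side in ("infant", "mother"):
            shared_vals = window[f"{side}_shared_mean"].dropna()
            non_vals = window[f"{side}_nonshared_mean"].dropna()
            if len(shared_vals) >= 1 and len(non_vals) >= 1:
                stat, p = stats.ranksums(shared_vals, non_vals)
            else:
                stat, p = float("nan"), float("nan")
            tests.append(
                {
                    "age_lo": lo,
                    "age_hi": hi,
                    "side": side,
                    "n_samples": len(window),
                    "statistic": float(stat),
                    "pvalue": float(p),
                    "shared_mean": float(shared_vals.mean()) if len(shared_vals) else float("nan"),
                    "nonshared_mean": float(non_vals.mean()) if len(non_vals) else float("nan"),
                }
            )
    return samples, pd.DataFrame(tests)


def sharing_rate_by_prevalence(
    cohort: Cohort,
    body_site: str,
    bin_edges: tuple[float, float] = (1e-3, 1e-4),
    min_reads: int = 1,
) -> pd.DataFrame:
    """Per-taxon dyad sharing rate vs infant prevalence, binned by maternal abundance.

    Infant prevalence: fraction of infant samples (at the site) containing the
    taxon. Dyad sharing rate: among infant samples containing the taxon whose
    dyad has same-site maternal samples, the fraction whose mother also carries
    it. Maternal mean abundance: mean relative abundance over all maternal
    same-site samples; binned at >0.1% / 0.01-0.1% / <=0.01% by default.
    """
    hi, lo = bin_edges
    if not (0 < lo < hi < 1):
        raise ValueError("bin_edges must satisfy 0 < lower < upper < 1")
    present = _present_matrix(cohort, min_reads)
    props = cohort.table.proportions()
    infant_cols = []
    mother_unions = []
    for rec in cohort.records_aligned():
        if rec.role != "infant" or rec.body_site != body_site or rec.dyad_id is None:
            continue
        union = _mother_union_same_site(cohort, present, rec.dyad_id, body_site)
        infant_cols.append(cohort.table.sample_index(rec.sample_id))
        mother_unions.append(union)
    with_mother = [k for k, u in enumerate(mother_unions) if u is not None]
    if len(with_mother) < 2:
        raise ValueError("need at least 2 infant samples with same-site maternal samples")

    mother_cols = [
        cohort.table.sample_index(r.sample_id)
        for r in cohort.records
        if r.role == "mother" and r.body_site == body_site
    ]
    maternal_mean = (
        props[:, mother_cols].mean(axis=1) if mother_cols else np.zeros(cohort.table.n_taxa)
    )

    infant_presence = present[:, infant_cols]
    prevalence = infant_presence.mean(axis=1)
    shared_counts = np.zeros(cohort.table.n_taxa)
    carrier_counts = np.zeros(cohort.table.n_taxa)
    for k in with_mother:
        carriers = infant_presence[:, k]
        carrier_counts += carriers
        shared_counts += carriers & mother_unions[k]
    rows = []
    for i, taxon in enumerate(cohort.table.taxon_ids):
        if prevalence[i] == 0:
            continue
        rate = shared_counts[i] / carrier_counts[i] if carrier_counts[i] else float("nan")
        ma = float(maternal_mean[i])
        if ma > hi:
            abin = ABUNDANCE_BINS[0]
        elif ma > lo:
            abin = ABUNDANCE_BINS[1]
        else:
            abin = ABUNDANCE_BINS[2]
        rows.append(
            {
                "taxon_id": taxon,
                "infant_prevalence": float(prevalence[i]),
                "dyad_sharing_rate": float(rate),
                "maternal_mean_abundance": ma,
                "abundance_bin": abin,
            }
        )
    return pd.DataFrame(rows)


def mother_pair_sharing(
    cohort: Cohort,
    body_site: str,
    statistic: str = "min_overlap",
    min_reads: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise taxon overlap between mothers, within vs between villages.

    Each mother's taxon set pools her samples at the site. ``min_overlap`` is
    ``|A ∩ B| / min(|A|, |B|)``; ``jaccard`` is offered as an alternative.
    Returns the pair table and a Wilcoxon rank-sum comparison of within- vs
    between-village overlaps.
    """
    if statistic not in ("min_overlap", "jaccard"):
        raise ValueError(f"unknown statistic {statistic!r}")
    present = _present_matrix(cohort, min_reads)
    mothers: dict[str, dict] = {}
    for rec in cohort.records_aligned():
        if rec.role != "mother" or rec.body_site != body_site:
            continue
        entry = mothers.setdefault(
            rec.subject_id, {"village": rec.village, "cols": []}
        )
        entry["cols"].append(cohort.table.sample_index(rec.sample_id))
    mothers = {s: e for s, e in mothers.items() if e["cols"] and e["village"] is not None}
    villages = {}
    for s, e in mothers.items():
        villages.setdefault(e["village"], []).append(s)
    if sum(1 for v in villages.values() if len(v) >= 2) < 2:
        raise ValueError("need >= 2 villages with >= 2 mothers each")

    sets = {
        s: set(np.flatnonzero(present[:, e["cols"]].any(axis=1)))
        for s, e in mothers.items()
    }
    subjects = sorted(mothers)
    rows = []
    for i, a in enumerate(subjects):
        for b in subjects[i + 1 :]:
            inter = len(sets[a] & sets[b])
            if statistic == "min_overlap":
                denom = min(len(sets[a]), len(sets[b]))
            else:
                denom = len(sets[a] | sets[b])
            rows.append(
                {
                    "mother_a": a,
                    "mother_b": b,
                    "same_village": mothers[a]["village"] == mothers[b]["village"],
                    "overlap": inter / denom if denom else float("nan"),
                }
            )
    pairs = pd.DataFrame(rows)
    within = pairs.loc[pairs.same_village, "overlap"].dropna()
    between = pairs.loc[~pairs.same_village, "overlap"].dropna()
    stat, p = stats.ranksums(within, between)
    report = {
        "statistic": float(stat),
        "pvalue": float(p),
        "within_mean": float(within.mean()),
        "between_mean": float(between.mean()),
        "n_within": int(len(within)),
        "n_between": int(len(between)),
        "overlap_statistic": statistic,
    }
    return pairs, report
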
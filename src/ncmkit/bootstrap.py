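"""One-sample-per-subject bootstrap of the neutral-model fit.

Longitudinal designs violate the model's assumption of independent local
communities: subjects sampled repeatedly would otherwise dominate both the
regional pool and the occurrence frequencies. Each permutation draws one sample
per subject uniformly at random, rebuilds the source pool and occurrence
frequencies from that draw, refits the model and classifies every eligible
taxon. The aggregate gives a bootstrapped estimate of model fit (RMSE mean and
standard deviation, distribution of fitted m) and, per taxon, the fraction of
permutations in which it was classified above / within / below the prediction
band, from which a consistency label (neutral / above / below / variable) is
derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import Z95, fit_ncm
from .tables import Cohort, build_source_pool, occurrence_frequency

__all__ = [
    "BootstrapConfig",
    "BootstrapSummary",
    "FitComparison",
    "one_per_subject_resample",
    "run_bootstrap",
    "consistent_classification",
    "compare_fit",
]

LABEL_NEUTRAL = "neutral"
LABEL_VARIABLE = "variable"

_PSEUDOREPLICATION_CAVEAT = (
    "bootstrap replicates are resamples of the same cohort, not independent "
    "observations; the p-value is descriptive"
)


@dataclass(frozen=True)
class BootstrapConfig:
    n_permutations: int = 1000
    consistency_threshold: float = 0.90
    seed: int = 0
    confidence_z: float = Z95

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.5 < self.consistency_threshold <= 1.0):
            raise ValueError("consistency_threshold must lie in (0.5, 1]")


def one_per_subject_resample(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Select one sample per subject, uniformly among that subject's samples."""
    chosen: list[str] = []
    for subject, samples in cohort.subjects().items():
        chosen.append(samples[int(rng.integers(len(samples)))] if len(samples) > 1 else samples[0])
    table = cohort.table.select_samples(chosen)
    by_id = cohort._by_id
    return Cohort(table, tuple(by_id[s] for s in chosen))


def consistent_classification(
    frac_above: float, frac_within: float, frac_below: float, threshold: float
) -> str:
    """Label a taxon from its per-permutation classification fractions.

    Threshold comparisons are inclusive ("in at least 90% of permutations").
    Only one class can reach a threshold > 0.5, so the order of checks is
    immaterial; taxa reaching no threshold are ``variable``.
    """
    if frac_within >= threshold:
        return LABEL_NEUTRAL
    if frac_above >= threshold:
        return "above"
    if frac_below >= threshold:
        return "below"
    return LABEL_VARIABLE


@dataclass(frozen=True)
class BootstrapSummary:
    """Aggregated one-per-subject bootstrap of the neutral-model fit.

    ``per_taxon`` carries, for every taxon with at least one read in the
    cohort: classification counts, fractions over all permutations (their sum
    falls short of 1 by the fraction of permutations where the taxon had pool
    abundance 0), fractions over fit-eligible permutations (the denominators
    behind the consistency labels), and the label itself.
    """

    rmse_values: np.ndarray
    m_values: np.ndarray
    per_taxon: pd.DataFrame
    n_permutations: int
    n_skipped: int
    config: BootstrapConfig
    pooling_rule: str

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.rmse_values))

    @property
    def rmse_sd(self) -> float:
        return float(np.std(self.rmse_values, ddof=1)) if len(self.rmse_values) > 1 else 0.0

    def label_fractions(self, denominator: str = "labeled") -> dict[str, float]:
        """Fraction of taxa per consistency label.

        ``denominator="labeled"`` uses all taxa in ``per_taxon``;
        ``denominator="ever_eligible"`` restricts to taxa that were
        fit-eligible in at least one permutation.
        """
        df = self.per_taxon
        if denominator == "ever_eligible":
            df = df[df["n_eligible"] > 0]
        elif denominator != "labeled":
            raise ValueError(f"unknown denominator {denominator!r}")
        total = len(df)
        return {
            label: float((df["label"] == label).sum()) / total if total else float("nan")
            for label in (LABEL_NEUTRAL, "above", "below", LABEL_VARIABLE)
        }


def run_bootstrap(
    cohort: Cohort,
    config: BootstrapConfig | None = None,
    pooling_rule: str = "pooled_counts",
    N: float | None = None,
    d: float | None = None,
    detection: str = "threshold",
    min_reads_detect: int = 1,
    fixed_pool: bool = False,
    max_skip_fraction: float = 0.20,
) -> BootstrapSummary:
    """Bootstrap the neutral-model fit over one-sample-per-subject permutations.

    Within each permutation the source pool, occurrence frequencies, N (mean
    read depth of the resampled set, unless overridden) and d (``1/N`` unless
    overridden) are all recomputed from the resampled samples. With
    ``fixed_pool=True`` the pool is built once from the full cohort instead
    (sensitivity mode). Fully reproducible from ``config.seed``: permutation i
    uses an RNG stream spawned deterministically at index i.
    """
    config = config or BootstrapConfig()
    taxon_ids = list(cohort.table.taxon_ids)
    n_taxa = len(taxon_ids)
    # taxa with zero counts everywhere can never be fit; drop them from the report
    ever_present = cohort.table.counts.sum(axis=1) > 0

    classes = ("above", "within", "below")
    counts = {c: np.zeros(n_taxa, dtype=np.int64) for c in classes}
    n_eligible = np.zeros(n_taxa, dtype=np.int64)
    rmse_values: list[float] = []
    m_values: list[float] = []
    n_skipped = 0

    full_pool = build_source_pool(cohort, pooling_rule) if fixed_pool else None
    children = np.random.SeedSequence(config.seed).spawn(config.n_permutations)
    index = {t: i for i, t in enumerate(taxon_ids)}

    for child in children:
        rng = np.random.default_rng(child)
        resampled = one_per_subject_resample(cohort, rng)
        pool = full_pool if fixed_pool else build_source_pool(resampled, pooling_rule)
        freq = occurrence_frequency(resampled, min_reads_detect)
        depths = resampled.table.depths()
        N_i = float(N) if N is not None else float(depths.mean())
        d_i = d  # None -> 1/N inside the fit
        try:
            fit = fit_ncm(
                pool,
                freq,
                N=N_i,
                d=d_i,
                confidence_z=config.confidence_z,
                n_obs=resampled.n_samples,
                detection=detection,
                depth=int(round(depths.mean())) if detection == "reads" else None,
                min_reads_detect=min_reads_detect,
            )
        except ValueError:
            n_skipped += 1
            continue
        rmse_values.append(fit.rmse)
        m_values.append(fit.params.m)
        for t in fit.taxa:
            i = index[t.taxon_id]
            n_eligible[i] += 1
            counts[t.classification][i] += 1

    if n_skipped > max_skip_fraction * config.n_permutations:
        raise ValueError(
            f"{n_skipped}/{config.n_permutations} permutations had fewer than 5 "
            "fit-eligible taxa; the cohort is too sparse to bootstrap"
        )

    n_run = config.n_permutations - n_skipped
    rows = []
    for i in np.flatnonzero(ever_present):
        ne = int(n_eligible[i])
        frac_all = {c: counts[c][i] / n_run if n_run else np.nan for c in classes}
        if ne > 0:
            frac_elig = {c: counts[c][i] / ne for c in classes}
            label = consistent_classification(
                frac_elig["above"],
                frac_elig["within"],
                frac_elig["below"],
                config.consistency_threshold,
            )
        else:
            frac_elig = {c: np.nan for c in classes}
            label = LABEL_VARIABLE
        rows.append(
            {
                "taxon_id": taxon_ids[i],
                "n_eligible": ne,
                **{f"n_{c}": int(counts[c][i]) for c in classes},
                **{f"frac_{c}": frac_all[c] for c in classes},
                **{f"frac_{c}_eligible": frac_elig[c] for c in classes},
                "label": label,
            }
        )
    per_taxon = pd.DataFrame(rows)
    return BootstrapSummary(
        rmse_values=np.asarray(rmse_values),
        m_values=np.asarray(m_values),
        per_taxon=per_taxon,
        n_permutations=config.n_permutations,
        n_skipped=n_skipped,
        config=config,
        pooling_rule=pooling_rule,
    )


@dataclass(frozen=True)
class FitComparison:
    """Welch two-sample t comparison of two bootstrap RMSE distributions."""

    statistic: float
    pvalue: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    caveat: str = _PSEUDOREPLICATION_CAVEAT


def compare_fit(summary_a: BootstrapSummary, summary_b: BootstrapSummary) -> FitComparison:
    """Welch t test on two bootstrap RMSE distributions (descriptive)."""
    a = np.asarray(summary_a.rmse_values, dtype=float)
    b = np.asarray(summary_b.rmse_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both summaries need at least 2 RMSE values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            stat, p = 0.0, 1.0
        else:
            stat = float(np.inf if np.mean(a) > np.mean(b) else -np.inf)
            p = 0.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(stat), float(p)
    return FitComparison(
        statistic=stat,
        pvalue=p,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )
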
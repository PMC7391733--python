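"""Ground-truth neutral (and optionally selective) community assembly simulator.

Two local-community generators share a metacommunity with long-tailed relative
abundances p:

* ``simulate_local_dirichlet`` draws the stationary composition of the Sloan
  model directly: ``x ~ Dirichlet(N m p)``. Fast, and analytically tied to the
  fitted model (each marginal is ``Beta(N m p_i, N m (1 - p_i))``), so it is
  the default generator for cohort-scale tests.
* ``simulate_local_agent`` runs the underlying Hubbell-style individual-based
  dynamics: a community of N discrete individuals in which one uniformly random
  individual dies per event and is replaced either by an immigrant drawn from p
  (probability m) or by the offspring of a surviving local individual drawn
  proportionally to local abundance times a per-taxon reproductive weight.
  Weights other than 1 break neutrality, giving ground truth for selection
  detection. The replacement draw excludes the just-removed individual (death
  before reproduction).

Sequencing is multinomial read sampling at a configurable (optionally
lognormal) depth. Cohorts are independent subject-time point assemblies;
mother-infant dyads mix each infant's immigration source between the mother's
community (weight ``dyad_alpha``) and a village pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, Cohort, SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MetacommunityConfig",
    "AssemblyConfig",
    "CohortSimConfig",
    "GroundTruth",
    "sample_metacommunity",
    "simulate_local_dirichlet",
    "simulate_local_agent",
    "sequence_sample",
    "simulate_cohort",
    "simulate_dyads",
    "ground_truth_frame",
]


@dataclass(frozen=True)
class MetacommunityConfig:
    """Metacommunity with a long-tailed abundance distribution.

    ``lognormal``: abundances proportional to exp(sigma * z), z standard
    normal — sigma about 2 gives the several-orders-of-magnitude spread typical
    of 16S surveys. ``geometric``: proportional to (1 - theta)^rank.
    """

    n_taxa: int = 300
    abundance_model: str = "lognormal"
    sigma: float = 2.0
    theta: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.abundance_model not in ("lognormal", "geometric"):
            raise ValueError(f"unknown abundance_model {self.abundance_model!r}")


@dataclass(frozen=True)
class AssemblyConfig:
    """Local-community assembly parameters.

    ``N``: individuals per local community; ``m``: per-death immigration
    probability; ``generations``: agent-model run length in multiples of N
    death-replacement events; ``selection_weights``: per-taxon reproductive
    weights (1 = neutral), used by the agent model only.

    With ``niche_targets=None`` the weights act as constant multiplicative
    advantages (directional selection). A constant advantage amplifies
    arrival and founder randomness, so across communities it *increases*
    abundance variance at matched mean — its occurrence-frequency signature is
    high abundance with patchy prevalence (at or below the neutral curve).
    Setting ``niche_targets`` to per-taxon target frequencies switches the
    weights to stabilizing (niche) selection: a taxon reproduces with weight
    ``w`` while below its target and ``1/w`` above it, pinning it near the
    target in every community. That is the regime whose signature is elevated
    prevalence at modest abundance — above the neutral curve.
    """

    N: int = 10_000
    m: float = 0.1
    generations: int = 50
    selection_weights: np.ndarray | None = None
    niche_targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if not (0 < self.m <= 1):
            raise ValueError("m must be in (0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.selection_weights is not None:
            w = np.asarray(self.selection_weights, dtype=float)
            if (w <= 0).any() or not np.isfinite(w).all():
                raise ValueError("selection weights must be positive and finite")
            object.__setattr__(self, "selection_weights", w)
        if self.niche_targets is not None:
            if self.selection_weights is None:
                raise ValueError("niche_targets require selection_weights")
            t = np.asarray(self.niche_targets, dtype=float)
            if ((t <= 0) | (t >= 1)).any() or not np.isfinite(t).all():
                raise ValueError("niche targets must lie in (0, 1)")
            object.__setattr__(self, "niche_targets", t)


@dataclass(frozen=True)
class CohortSimConfig:
    n_subjects: int = 50
    samples_per_subject: int = 1
    read_depth: int = 5000
    depth_sigma: float = 0.0  # lognormal spread of per-sample depth; 0 = fixed
    country: str = "Simland"
    body_site: str = "stool"
    age_range: tuple[float, float] = (1.0, 13.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.samples_per_subject < 1:
            raise ValueError("samples_per_subject must be >= 1")
        if self.read_depth < 100:
            raise ValueError("read_depth must be >= 100")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth for recovery tests."""

    taxon_ids: tuple[str, ...]
    p: np.ndarray
    m_true: float
    selection_labels: tuple[str, ...]
    dyad_alpha: float | None = None


def _labels_from_weights(n_taxa: int, weights: np.ndarray | None) -> tuple[str, ...]:
    if weights is None:
        return tuple(["neutral"] * n_taxa)
    out = []
    for w in weights:
        out.append("positive" if w > 1 else ("negative" if w < 1 else "neutral"))
    return tuple(out)


def sample_metacommunity(config: MetacommunityConfig) -> np.ndarray:
    """Draw strictly positive metacommunity proportions summing to 1."""
    rng = np.random.default_rng(config.seed)
    if config.abundance_model == "lognormal":
        raw = np.exp(config.sigma * rng.standard_normal(config.n_taxa))
    else:
        ranks = np.arange(config.n_taxa)
        raw = config.theta * (1 - config.theta) ** ranks
        raw = rng.permutation(raw)
    p = raw / raw.sum()
    # guard against underflow to exact zero in extreme tails
    p = np.maximum(p, np.finfo(float).tiny)
    return p / p.sum()


def simulate_local_dirichlet(
    p: np.ndarray, N: float, m: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Sloan composition: Dirichlet with concentration ``N m p``.

    Sampled through independent gammas so that very small concentration
    parameters (strong drift) remain well behaved.
    """
    alpha = np.asarray(p, dtype=float) * N * m
    if (alpha <= 0).any():
        raise ValueError("N * m * p must be positive for every taxon")
    draws = rng.gamma(alpha)
    total = draws.sum()
    if total == 0.0:  # all gammas underflowed: community fixes on one taxon
        x = np.zeros_like(alpha)
        x[rng.choice(len(alpha), p=p / p.sum())] = 1.0
        return x
    return draws / total


def simulate_local_agent(
    p: np.ndarray, config: AssemblyConfig, rng: np.random.Generator
) -> np.ndarray:
    """Individual-based neutral/selective assembly; returns integer abundances.

    Runs ``config.generations * config.N`` death-replacement events from a
    multinomial draw of the metacommunity. Community size is conserved at every
    step. A crude stationarity diagnostic (correlation between the composition
    at the midpoint and at the end) is logged at DEBUG level.
    """
    p = np.asarray(p, dtype=float)
    N, m = config.N, config.m
    weights = (
        np.ones_like(p)
        if config.selection_weights is None
        else np.asarray(config.selection_weights, dtype=float)
    )
    if weights.shape != p.shape:
        raise ValueError("selection weights must align with the metacommunity")
    targets = config.niche_targets
    counts = rng.multinomial(N, p).astype(np.int64)
    n_events = config.generations * N
    # batched uniforms keep the per-event cost down
    u_death = rng.random(n_events)
    u_mode = rng.random(n_events)
    u_repl = rng.random(n_events)
    p_cum = np.cumsum(p)
    p_cum[-1] = 1.0
    halfway_counts = None
    for t in range(n_events):
        cum = np.cumsum(counts)
        dead = int(np.searchsorted(cum, u_death[t] * N, side="right"))
        counts[dead] -= 1
        if u_mode[t] < m:
            born = int(np.searchsorted(p_cum, u_repl[t], side="right"))
        else:
            if targets is None:
                w_eff = weights
            else:
                # stabilizing: advantaged below target, penalised above it
                w_eff = np.where(counts < targets * N, weights, 1.0 / weights)
            wcum = np.cumsum(counts * w_eff)
            born = int(np.searchsorted(wcum, u_repl[t] * wcum[-1], side="right"))
        counts[born] += 1
        if t == n_events // 2:
            halfway_counts = counts.copy()
    if halfway_counts is not None and logger.isEnabledFor(logging.DEBUG):
        corr = float(np.corrcoef(halfway_counts, counts)[0, 1])
        logger.debug("agent run: midpoint/end composition correlation %.3f", corr)
    return counts


def sequence_sample(
    composition: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read sampling of a composition; counts sum to ``depth``."""
    comp = np.asarray(composition, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if abs(comp.sum() - 1.0) > 1e-8 or (comp < 0).any():
        raise ValueError("composition must be nonnegative and sum to 1")
    return rng.multinomial(int(depth), comp / comp.sum())


def _draw_depth(cfg: CohortSimConfig, rng: np.random.Generator) -> int:
    if cfg.depth_sigma <= 0:
        return cfg.read_depth
    mu = math.log(cfg.read_depth) - cfg.depth_sigma**2 / 2  # mean-preserving
    return max(100, int(round(rng.lognormal(mu, cfg.depth_sigma))))


def _taxon_ids(n: int) -> tuple[str, ...]:
    return tuple(f"ASV{i:04d}" for i in range(n))


def simulate_cohort(
    meta: MetacommunityConfig,
    assembly: AssemblyConfig,
    cohort_cfg: CohortSimConfig,
    method: str = "dirichlet",
) -> tuple[Cohort, GroundTruth]:
    """Simulate a longitudinal single-site cohort of independent local communities.

    Each subject-time point is an independent assembly run sharing the same
    metacommunity and migration rate, sequenced to the configured depth.
    ``method="dirichlet"`` uses the stationary shortcut (neutral only);
    ``method="agent"`` runs the individual-based dynamics and honours
    ``assembly.selection_weights``.
    """
    if method not in ("dirichlet", "agent"):
        raise ValueError(f"unknown method {method!r}")
    if method == "dirichlet" and assembly.selection_weights is not None:
        raise ValueError(
            "selection weights require the agent method; the Dirichlet shortcut is neutral"
        )
    p = sample_metacommunity(meta)
    rng = np.random.default_rng(np.random.SeedSequence(cohort_cfg.seed).spawn(1)[0])
    taxa = _taxon_ids(meta.n_taxa)
    columns = []
    sample_ids = []
    records = []
    age_lo, age_hi = cohort_cfg.age_range
    for s in range(cohort_cfg.n_subjects):
        subject = f"S{s:03d}"
        ages = np.sort(rng.uniform(age_lo, age_hi, cohort_cfg.samples_per_subject))
        for t in range(cohort_cfg.samples_per_subject):
            if method == "dirichlet":
                comp = simulate_local_dirichlet(p, assembly.N, assembly.m, rng)
            else:
                counts = simulate_local_agent(p, assembly, rng)
                comp = counts / counts.sum()
            depth = _draw_depth(cohort_cfg, rng)
            reads = sequence_sample(comp, depth, rng)
            sid = f"{subject}_T{t}"
            sample_ids.append(sid)
            columns.append(reads)
            records.append(
                SampleRecord(
                    sample_id=sid,
                    subject_id=subject,
                    role="infant",
                    body_site=cohort_cfg.body_site,
                    age_months=float(ages[t]),
                    country=cohort_cfg.country,
                    village="V1",
                    village_type="forest",
                )
            )
    table = AbundanceTable(taxa, tuple(sample_ids), np.column_stack(columns))
    truth = GroundTruth(
        taxon_ids=taxa,
        p=p,
        m_true=assembly.m,
        selection_labels=_labels_from_weights(meta.n_taxa, assembly.selection_weights),
    )
    return Cohort(table, tuple(records)), truth


def simulate_dyads(
    meta: MetacommunityConfig,
    assembly: AssemblyConfig,
    cohort_cfg: CohortSimConfig,
    dyad_alpha: float = 0.5,
    n_villages: int = 2,
    village_concentration: float = 500.0,
    mother_samples_per_subject: int = 1,
) -> tuple[Cohort, GroundTruth]:
    """Simulate mother-infant dyads with a mixed maternal/village immigration source.

    Village pools are Dirichlet perturbations of the metacommunity
    (concentration ``village_concentration``; larger = more similar villages).
    Mothers assemble from their village pool; each infant's immigration source
    is ``dyad_alpha * mother + (1 - dyad_alpha) * village pool``. With
    ``dyad_alpha=0`` infants are exchangeable with unrelated village infants;
    with ``dyad_alpha=1`` every immigrant is maternally derived.
    """
    if not (0 <= dyad_alpha <= 1):
        raise ValueError("dyad_alpha must lie in [0, 1]")
    if n_villages < 1:
        raise ValueError("n_villages must be >= 1")
    p = sample_metacommunity(meta)
    rng = np.random.default_rng(np.random.SeedSequence(cohort_cfg.seed).spawn(1)[0])
    taxa = _taxon_ids(meta.n_taxa)
    village_pools = []
    for _ in range(n_villages):
        draws = rng.gamma(village_concentration * p)
        draws = np.maximum(draws, np.finfo(float).tiny)
        village_pools.append(draws / draws.sum())

    columns, sample_ids, records = [], [], []
    age_lo, age_hi = cohort_cfg.age_range

    def emit(sid, subject, role, age, dyad, village, comp):
        depth = _draw_depth(cohort_cfg, rng)
        columns.append(sequence_sample(comp, depth, rng))
        sample_ids.append(sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                subject_id=subject,
                role=role,
                body_site=cohort_cfg.body_site,
                age_months=age,
                country=cohort_cfg.country,
                dyad_id=dyad,
                village=village,
                village_type="forest",
            )
        )

    for k in range(cohort_cfg.n_subjects):
        dyad = f"D{k:03d}"
        village_idx = k % n_villages
        village = f"V{village_idx}"
        pool = village_pools[village_idx]
        mother_comp = simulate_local_dirichlet(pool, assembly.N, assembly.m, rng)
        for t in range(mother_samples_per_subject):
            emit(f"M{k:03d}_T{t}", f"M{k:03d}", "mother", 300.0, dyad, village, mother_comp)
        source = dyad_alpha * mother_comp + (1 - dyad_alpha) * pool
        source = np.maximum(source, np.finfo(float).tiny)
        source = source / source.sum()
        ages = np.sort(rng.uniform(age_lo, min(age_hi, 18.0), cohort_cfg.samples_per_subject))
        for t in range(cohort_cfg.samples_per_subject):
            comp = simulate_local_dirichlet(source, assembly.N, assembly.m, rng)
            emit(f"I{k:03d}_T{t}", f"I{k:03d}", "infant", float(ages[t]), dyad, village, comp)

    table = AbundanceTable(taxa, tuple(sample_ids), np.column_stack(columns))
    truth = GroundTruth(
        taxon_ids=taxa,
        p=p,
        m_true=assembly.m,
        selection_labels=_labels_from_weights(meta.n_taxa, None),
        dyad_alpha=dyad_alpha,
    )
    return Cohort(table, tuple(records)), truth


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": list(truth.taxon_ids),
            "p": truth.p,
            "m_true": truth.m_true,
            "selection_label": list(truth.selection_labels),
            "dyad_alpha": truth.dyad_alpha if truth.dyad_alpha is not None else "",
        }
    )
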
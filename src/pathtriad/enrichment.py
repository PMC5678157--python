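"""Gene-set enrichment engine for ranked protein ratio profiles.

The engine implements the weighted Kolmogorov–Smirnov running-sum statistic
on a profile ranked by log2 ratio ("difference of classes" between the two
cell types):

* proteins are sorted by descending log2 ratio (ties broken
  lexicographically by symbol so the order is reproducible);
* for a pathway with ``Nh`` members mapped into the ranked list of ``N``
  proteins, a running sum increments at member positions by
  ``|metric|**p / sum(|metric|**p over members)`` and decrements at
  non-member positions by ``1 / (N - Nh)``;
* the enrichment score ES is the running-sum extremum of largest magnitude
  (positive preferred on an exact tie), and the *leading edge* is the set
  of members at or before the extremum (at or after it, for negative ES);
* the null distribution is built by *gene_set permutation*: rescoring
  uniformly random same-size subsets of the ranked universe;
* NES divides ES by the mean magnitude of same-sign null scores, the
  nominal p is the same-sign null tail fraction, and the FDR q-value is the
  sign-stratified ratio-of-tails estimator over the pooled normalized null
  scores.

Pathways mapping fewer than ``min_size`` or more than ``max_size`` profile
proteins are reported but flagged ``tested=False`` (their mapped count is
still recorded, which the three-way comparison needs to distinguish
"not tested" from "tested but not significant").
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pathtriad.profile_io import GeneSetCollection, ProteinRatioProfile

logger = logging.getLogger(__name__)

UP, DOWN = "UP", "DOWN"

#: Magnitude difference below which the positive and negative running-sum
#: extrema are treated as tied (the positive one is then preferred).  The
#: tie is mathematical — e.g. a member block in the exact middle of the
#: list gives extrema of +x and -x — but the two magnitudes are computed
#: along different floating-point paths, so the comparison needs slack.
ES_TIE_EPS = 1e-9


@dataclass(frozen=True)
class GseaConfig:
    """Parameters of the enrichment analysis.

    Defaults follow common practice for ratio-profile enrichment: pathway
    size window 20–200 mapped proteins, 1000 gene_set permutations,
    significance at FDR < 25%, weight exponent ``p=1`` (the weighted
    statistic; ``p=0`` gives the classical unweighted KS form).
    ``exhaustive=True`` replaces random sampling by complete enumeration of
    all same-size subsets when there are at most ``max_exhaustive`` of
    them; beyond that, a seeded sample of ``max_exhaustive`` subsets is
    drawn instead (capped enumeration).
    """

    min_size: int = 20
    max_size: int = 200
    n_perm: int = 1000
    fdr_threshold: float = 0.25
    weight_exponent: float = 1.0
    rng_seed: int = 0
    exhaustive: bool = False
    max_exhaustive: int = 100_000

    def __post_init__(self) -> None:
        if not (0 < self.min_size <= self.max_size):
            raise ValueError("need 0 < min_size <= max_size")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")


@dataclass(frozen=True)
class RankedList:
    """Gene symbols sorted by descending ranking metric (log2 ratio)."""

    symbols: tuple[str, ...]
    metrics: np.ndarray  # float array aligned with symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def positions(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 0-based ranks of the given symbols (absent ones ignored)."""
        index = {s: i for i, s in enumerate(self.symbols)}
        pos = sorted(index[m] for m in members if m in index)
        return np.asarray(pos, dtype=np.intp)


@dataclass(frozen=True)
class EnrichmentScore:
    """ES with its full running sum and the leading-edge members."""

    es: float
    running_sum: np.ndarray
    leading_edge: tuple[str, ...]
    peak_index: int


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment outcome.

    ``tested=False`` (pathway size outside the configured window) implies
    all score fields are ``None``; ``p_below_resolution`` marks a nominal p
    smaller than the permutation resolution (reported as 0.0).
    """

    pathway: str
    mapped_n: int
    tested: bool
    source: str = ""
    es: float | None = None
    nes: float | None = None
    p_nominal: float | None = None
    fdr: float | None = None
    direction: str | None = None
    leading_edge: tuple[str, ...] = ()
    p_below_resolution: bool = False
    significant: bool = False


def rank_proteins(profile: ProteinRatioProfile) -> RankedList:
    """Rank every profile protein by descending log2 ratio.

    No abundance or fold-change filtering is applied: all quantified
    proteins contribute.  Ties are broken by lexicographic symbol order, so
    the ranking is a pure function of the record set.
    """
    if len(profile) == 0:
        raise ValueError(f"profile {profile.name!r} is empty")
    items = sorted(
        profile.records.items(), key=lambda kv: (-kv[1].log2_ratio, kv[0])
    )
    symbols = tuple(sym for sym, _ in items)
    metrics = np.array([rec.log2_ratio for _, rec in items], dtype=float)
    return RankedList(symbols=symbols, metrics=metrics)


def _hit_weights(metrics: np.ndarray, p: float) -> np.ndarray:
    return np.abs(metrics) ** p


def enrichment_score(
    ranked: RankedList, members: Iterable[str], p: float = 1.0
) -> EnrichmentScore:
    """Running-sum enrichment score of a member set against a ranked list.

    If every mapped member has a zero metric (so the weighted increments
    are undefined), increments fall back to the unweighted ``1/Nh`` form.
    """
    member_set = set(members)
    n = len(ranked)
    hit = np.fromiter((s in member_set for s in ranked.symbols), bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("no member of the set appears in the ranked list")
    if n_hit == n:
        raise ValueError("the set covers the entire ranked list; ES undefined")
    weights = _hit_weights(ranked.metrics, p)
    total = math.fsum(weights[hit])  # correctly-rounded sum: order-independent
    steps = np.empty(n, dtype=float)
    if total > 0:
        steps[hit] = weights[hit] / total
    else:  # degenerate all-zero metrics among members
        steps[hit] = 1.0 / n_hit
    steps[~hit] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min] - ES_TIE_EPS:
        es, peak = float(running[i_max]), i_max
        leading = tuple(
            ranked.symbols[i] for i in range(peak + 1) if hit[i]
        )
    else:
        es, peak = float(running[i_min]), i_min
        leading = tuple(
            ranked.symbols[i] for i in range(peak, n) if hit[i]
        )
    return EnrichmentScore(es=es, running_sum=running, leading_edge=leading, peak_index=peak)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many member-position sets at once.

    ``positions`` is a (B, k) integer array of sorted 0-based ranks;
    ``weights`` holds ``|metric|**p`` for every rank of the list.  Between
    member positions the running sum decreases linearly, so its extrema can
    only occur immediately after a member (candidate maxima) or immediately
    before one (candidate minima, plus the final return to zero).
    """
    b, k = positions.shape
    if k >= n:
        raise ValueError("set size must be smaller than the universe")
    w = weights[positions]
    total = w.sum(axis=1, keepdims=True)
    uniform = total <= 0
    if np.any(uniform):
        w = np.where(uniform, 1.0 / k, w / np.where(uniform, 1.0, total))
    else:
        w = w / total
    cum = np.cumsum(w, axis=1)  # value contributed by members up to hit j
    miss_penalty = (positions - np.arange(k)) / (n - k)  # misses before hit j
    after = cum - miss_penalty
    before = np.concatenate([np.zeros((b, 1)), cum[:, :-1]], axis=1) - miss_penalty
    es_max = after.max(axis=1)
    es_min = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_max >= -es_min - ES_TIE_EPS, es_max, es_min)


def _pathway_rng(seed: int, stream_key: str | None) -> np.random.Generator:
    """One RNG stream per pathway, derived from the master seed.

    The stream depends only on ``(seed, stream_key)``, never on evaluation
    order, so per-pathway null samples are reproducible in isolation.
    """
    if stream_key is None:
        return np.random.default_rng(np.random.SeedSequence(seed))
    key = zlib.crc32(stream_key.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def permutation_null(
    ranked: RankedList,
    set_size: int,
    cfg: GseaConfig,
    stream_key: str | None = None,
) -> np.ndarray:
    """Null ES sample under gene_set permutation.

    Each draw rescoring a uniformly random ``set_size``-subset of the
    ranked universe (sampling without replacement).  With
    ``cfg.exhaustive`` every subset is enumerated instead, yielding the
    exact permutation distribution.
    """
    n = len(ranked)
    if set_size >= n:
        raise ValueError(f"set_size {set_size} must be < universe size {n}")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    weights = _hit_weights(ranked.metrics, cfg.weight_exponent)
    n_draws = cfg.n_perm
    if cfg.exhaustive:
        n_subsets = math.comb(n, set_size)
        if n_subsets <= cfg.max_exhaustive:
            positions = np.array(
                list(combinations(range(n), set_size)), dtype=np.intp
            )
            return _es_from_positions(positions, weights, n)
        # capped enumeration: too many subsets, take a seeded random sample
        logger.info(
            "C(%d,%d)=%d subsets exceed max_exhaustive=%d; sampling that many",
            n, set_size, n_subsets, cfg.max_exhaustive,
        )
        n_draws = cfg.max_exhaustive
    rng = _pathway_rng(cfg.rng_seed, stream_key)
    draws = rng.random((n_draws, n))
    positions = np.argpartition(draws, set_size - 1, axis=1)[:, :set_size]
    positions = np.sort(positions, axis=1)
    return _es_from_positions(positions, weights, n)


def normalize_and_fdr(
    observed: Sequence[EnrichmentResult],
    nulls: Mapping[str, np.ndarray],
    fdr_threshold: float = 0.25,
) -> list[EnrichmentResult]:
    """Fill NES, nominal p and FDR q-values on tested results (in place).

    Sign-stratified scheme: for a positive (negative) ES the nominal p is
    the fraction of positive (negative) null scores at least as extreme,
    and NES divides ES by the mean magnitude of the same-sign null scores.
    Null scores are normalized per pathway the same way and pooled; the FDR
    for an observed NES* is
    ``[fraction of pooled same-sign null NES >= NES*] /
    [fraction of observed same-sign NES >= NES*]`` (mirrored for negative
    scores), capped at 1.
    """
    tested = [r for r in observed if r.tested]
    pool_pos: list[np.ndarray] = []
    pool_neg: list[np.ndarray] = []
    for r in tested:
        if r.pathway not in nulls:
            raise ValueError(f"no null sample for tested pathway {r.pathway!r}")
        null_es = np.asarray(nulls[r.pathway], dtype=float)
        pos = null_es[null_es > 0]
        neg = null_es[null_es < 0]
        same = pos if r.es > 0 else neg
        if len(same) == 0:
            # no same-sign null score at all: below permutation resolution
            r.p_nominal = 0.0
            r.p_below_resolution = True
            scale = float(np.abs(null_es).mean()) if len(null_es) else 1.0
            r.nes = r.es / scale if scale > 0 else float(np.sign(r.es))
        else:
            if r.es > 0:
                count = int((same >= r.es - ES_TIE_EPS).sum())
            else:
                count = int((same <= r.es + ES_TIE_EPS).sum())
            r.p_nominal = count / len(same)
            r.p_below_resolution = count == 0
            scale = float(np.abs(same).mean())
            r.nes = r.es / scale
        if len(pos):
            pool_pos.append(pos / pos.mean())
        if len(neg):
            pool_neg.append(neg / np.abs(neg).mean())
    null_nes_pos = np.concatenate(pool_pos) if pool_pos else np.empty(0)
    null_nes_neg = np.concatenate(pool_neg) if pool_neg else np.empty(0)
    obs_pos = np.array([r.nes for r in tested if r.nes is not None and r.nes > 0])
    obs_neg = np.array([r.nes for r in tested if r.nes is not None and r.nes <= 0])
    for r in tested:
        if r.nes is None:
            continue
        if r.nes > 0:
            num = (null_nes_pos >= r.nes).mean() if len(null_nes_pos) else 0.0
            den = (obs_pos >= r.nes).mean()
        else:
            num = (null_nes_neg <= r.nes).mean() if len(null_nes_neg) else 0.0
            den = (obs_neg <= r.nes).mean()
        r.fdr = min(1.0, float(num / den)) if den > 0 else 0.0
        r.significant = r.fdr < fdr_threshold
    return list(observed)


def run_gsea(
    profile: ProteinRatioProfile,
    sets: GeneSetCollection,
    cfg: GseaConfig | None = None,
) -> list[EnrichmentResult]:
    """Score every pathway of a collection against one ratio profile.

    Pathway members absent from the profile are ignored; ``mapped_n``
    counts only the members present.  Pathways whose mapped count falls
    outside ``[min_size, max_size]`` are returned untested.  Tested results
    are sorted up-regulated first, then by ascending FDR; untested ones
    follow alphabetically.
    """
    cfg = cfg or GseaConfig()
    ranked = rank_proteins(profile)
    degenerate_ranking = bool(np.all(ranked.metrics == ranked.metrics[0]))
    if degenerate_ranking:
        logger.warning(
            "profile %r has a constant ranking metric; the protein order is "
            "pure tie-breaking, so no pathway can be called significant",
            profile.name,
        )
    universe = set(ranked.symbols)
    results: list[EnrichmentResult] = []
    nulls: dict[str, np.ndarray] = {}
    for pathway in sorted(sets.sets):
        mapped = sets.sets[pathway] & universe
        n_mapped = len(mapped)
        tested = cfg.min_size <= n_mapped <= cfg.max_size and n_mapped < len(universe)
        result = EnrichmentResult(
            pathway=pathway, mapped_n=n_mapped, tested=tested, source=sets.source
        )
        if tested:
            score = enrichment_score(ranked, mapped, cfg.weight_exponent)
            result.es = score.es
            result.direction = UP if score.es > 0 else DOWN
            result.leading_edge = score.leading_edge
            nulls[pathway] = permutation_null(
                ranked, n_mapped, cfg, stream_key=pathway
            )
        results.append(result)
    if not nulls:
        logger.warning(
            "no pathway of %r is testable against profile %r "
            "(size window %d-%d)",
            sets.source,
            profile.name,
            cfg.min_size,
            cfg.max_size,
        )
    normalize_and_fdr(results, nulls, cfg.fdr_threshold)
    if degenerate_ranking:
        # any apparent enrichment is an artifact of lexicographic tie-breaks
        for r in results:
            if r.tested:
                r.p_nominal = 1.0
                r.fdr = 1.0
                r.p_below_resolution = False
                r.significant = False
    tested_sorted = sorted(
        (r for r in results if r.tested),
        key=lambda r: (0 if r.direction == UP else 1, r.fdr, r.pathway),
    )
    untested_sorted = sorted(
        (r for r in results if not r.tested), key=lambda r: r.pathway
    )
    return tested_sorted + untested_sorted


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per pathway)."""
    rows = []
    for r in results:
        rows.append(
            {
                "pathway": r.pathway,
                "source": r.source,
                "mapped_n": r.mapped_n,
                "ES": r.es,
                "NES": r.nes,
                "p_nominal": r.p_nominal,
                "fdr": r.fdr,
                "direction": r.direction,
                "tested": r.tested,
                "significant": r.significant,
                "leading_edge": ",".join(r.leading_edge),
            }
        )
    return pd.DataFrame(rows)
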
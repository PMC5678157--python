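"""Synthetic comparative-proteomics data with planted regulation patterns.

The generator emulates the statistical structure the analysis assumes:

* a protein universe on the scale of a membrane-proteomics experiment
  (~1100 quantifiable proteins), with per-protein detectability so that
  technical replicates and different samples have overlapping-but-unequal
  protein sets;
* three latent comparison values per protein — the two pluripotent-vs-
  somatic log2 ratios and the pluripotent-vs-pluripotent ("delta") ratio,
  with the delta ratio tightly concentrated near zero (the two pluripotent
  cell types are nearly identical) and the vs-somatic ratios drawn from a
  heavy-shouldered zero-centred mixture;
* planted gene sets whose members carry coherent mean shifts following the
  incomplete-repression / incomplete-activation / common-up / common-down
  patterns (members of a planted set share the exact pattern triple, so
  ground-truth recovery is well defined);
* eight technical-replicate pairs (one per comparison sample) with
  independent Gaussian noise on the log2 scale and an optional fraction of
  shared proteins forced into the sign-conflict regime that the
  technical-merge rule removes;
* random null gene sets and a scored interaction edge list in which each
  planted set forms a high-confidence connected module.

Everything is reproducible from ``rng_seed``; the ground truth is returned
alongside the data (and serialized next to fixture files).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from pathtriad.integration import (
    EIGHT_ROLES,
    IntegrationConfig,
    merge_technical_replicates,
)
from pathtriad.ppi import ScoredEdgeList, write_edge_list
from pathtriad.profile_io import (
    GeneSetCollection,
    ProteinRatioProfile,
    ProteinRecord,
    write_gmt,
    write_profile,
)
from pathtriad.threeway import (
    COMMON_DOWN,
    COMMON_UP,
    INCOMPLETE_ACTIVATION,
    INCOMPLETE_REPRESSION,
)

_PATTERN_CATEGORIES = (
    INCOMPLETE_REPRESSION,
    INCOMPLETE_ACTIVATION,
    COMMON_UP,
    COMMON_DOWN,
)


@dataclass(frozen=True)
class PlantedPattern:
    """One planted gene set and its regulation pattern.

    ``effect_hff`` is the magnitude (log2 units) of the shift in the two
    vs-somatic comparisons; ``effect_delta`` the magnitude of the residual
    shift in the pluripotent-vs-pluripotent comparison.  Defaults mirror
    the magnitudes typical of incompletely regulated membrane pathways:
    about two log2 units against the somatic precursor and ~0.4 between the
    two pluripotent cell types.
    """

    name: str
    category: str
    size: int = 30
    effect_hff: float = 2.0
    effect_delta: float = 0.4

    def __post_init__(self) -> None:
        if self.category not in _PATTERN_CATEGORIES:
            raise ValueError(
                f"category must be one of {_PATTERN_CATEGORIES}, got {self.category!r}"
            )
        if self.size < 1:
            raise ValueError("size must be positive")

    def effects(self) -> tuple[float, float, float]:
        """True (delta, ips-vs-somatic, es-vs-somatic) log2 shifts.

        The vs-somatic shifts are split symmetrically around
        ``effect_hff`` so that the difference of the two equals the delta
        shift exactly (the three comparisons stay internally consistent:
        ips/somatic - es/somatic = ips/es on the log2 scale).
        """
        d, h = self.effect_delta, self.effect_hff
        if self.category == INCOMPLETE_REPRESSION:
            return (d, -(h - d / 2), -(h + d / 2))
        if self.category == INCOMPLETE_ACTIVATION:
            return (-d, h - d / 2, h + d / 2)
        if self.category == COMMON_UP:
            return (0.0, h, h)
        return (0.0, -h, -h)


def _default_patterns() -> tuple[PlantedPattern, ...]:
    return (
        PlantedPattern("PLANTED_INCOMPLETE_REPRESSION", INCOMPLETE_REPRESSION),
        PlantedPattern("PLANTED_INCOMPLETE_ACTIVATION", INCOMPLETE_ACTIVATION),
        PlantedPattern("PLANTED_COMMON_UP", COMMON_UP),
        PlantedPattern("PLANTED_COMMON_DOWN", COMMON_DOWN),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the package's study conditions.

    ``replicate_overlap`` is the expected ``|A ∩ B| / |A|`` between the two
    runs of a technical-replicate pair.  ``core_fraction`` of the universe
    is detected in every sample; the remainder gets a per-protein
    detectability drawn uniformly from ``peripheral_detect_range`` and is
    detected independently per sample.  Planted-set members are always
    detectable so planted set sizes are exact in every profile.
    """

    n_proteins: int = 1100
    replicate_overlap: float = 0.8
    noise_sd: float = 0.2
    conflict_rate: float = 0.01
    n_null_sets: int = 30
    set_size_range: tuple[int, int] = (25, 80)
    planted: tuple[PlantedPattern, ...] = field(default_factory=_default_patterns)
    core_fraction: float = 0.5
    peripheral_detect_range: tuple[float, float] = (0.2, 0.9)
    delta_narrow_sd: float = 0.15
    delta_wide_sd: float = 0.6
    hff_narrow_sd: float = 0.35
    hff_wide_sd: float = 1.3
    narrow_weight: float = 0.85
    n_background_edges: int = 2000
    conflict_threshold: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.replicate_overlap <= 1):
            raise ValueError("replicate_overlap must be in (0, 1]")
        if self.noise_sd < 0 or self.conflict_rate < 0:
            raise ValueError("noise_sd and conflict_rate must be non-negative")
        if not (0 <= self.core_fraction <= 1):
            raise ValueError("core_fraction must be in [0, 1]")
        total_planted = sum(p.size for p in self.planted)
        if total_planted > self.n_proteins:
            raise ValueError(
                f"planted sets need {total_planted} proteins but the universe "
                f"has only {self.n_proteins}"
            )


@dataclass(frozen=True)
class PlantedSetTruth:
    """Ground truth of one planted set."""

    name: str
    category: str
    members: tuple[str, ...]
    effects: tuple[float, float, float]  # (delta, ips, es) true shifts


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset (planted sets only)."""

    patterns: tuple[PlantedSetTruth, ...]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": p.name,
                "category": p.category,
                "members": list(p.members),
                "effects": list(p.effects),
            }
            for p in self.patterns
        ]
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            patterns=tuple(
                PlantedSetTruth(
                    name=p["name"],
                    category=p["category"],
                    members=tuple(p["members"]),
                    effects=tuple(p["effects"]),
                )
                for p in payload
            )
        )


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus ground truth."""

    eight: dict[str, ProteinRatioProfile]
    technical_pairs: dict[str, tuple[ProteinRatioProfile, ProteinRatioProfile]]
    gene_sets: GeneSetCollection
    edges: ScoredEdgeList
    truth: SyntheticTruth
    true_profiles: dict[str, ProteinRatioProfile]


def _mixture(
    rng: np.random.Generator,
    n: int,
    narrow_sd: float,
    wide_sd: float,
    narrow_weight: float,
) -> np.ndarray:
    """Zero-centred two-component Gaussian mixture (spike + shoulders)."""
    narrow = rng.random(n) < narrow_weight
    values = np.where(
        narrow, rng.normal(0.0, narrow_sd, n), rng.normal(0.0, wide_sd, n)
    )
    return values


def _profile_from_values(
    name: str, symbols: Sequence[str], values: Mapping[str, float]
) -> ProteinRatioProfile:
    records = {
        s: ProteinRecord(f"ACC_{s}", s, float(values[s])) for s in sorted(symbols)
    }
    return ProteinRatioProfile(name=name, records=records)


#: True comparison underlying each of the eight sample roles.
_ROLE_COMPARISON = {
    "ips1_vs_hff": "ips",
    "ips2_vs_hff": "ips",
    "es1_vs_hff": "es",
    "es2_vs_hff": "es",
    "ips1_vs_es1": "delta",
    "ips2_vs_es1": "delta",
    "ips1_vs_es2": "delta",
    "ips2_vs_es2": "delta",
}


def generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset under ``cfg`` (reproducible)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed))
    n = cfg.n_proteins
    width = max(5, len(str(n)))
    symbols = np.array([f"SYN{i:0{width}d}" for i in range(n)])

    # --- latent true comparison values -------------------------------------
    t_eh = _mixture(rng, n, cfg.hff_narrow_sd, cfg.hff_wide_sd, cfg.narrow_weight)
    t_ie = _mixture(rng, n, cfg.delta_narrow_sd, cfg.delta_wide_sd, cfg.narrow_weight)
    t_ih = t_eh + t_ie

    # --- planted sets: disjoint member blocks with exact pattern triples ---
    order = rng.permutation(n)
    cursor = 0
    truths: list[PlantedSetTruth] = []
    planted_idx: list[np.ndarray] = []
    for pattern in cfg.planted:
        idx = order[cursor : cursor + pattern.size]
        cursor += pattern.size
        delta_eff, ips_eff, es_eff = pattern.effects()
        t_ie[idx] = delta_eff
        t_ih[idx] = ips_eff
        t_eh[idx] = es_eff
        planted_idx.append(idx)
        truths.append(
            PlantedSetTruth(
                name=pattern.name,
                category=pattern.category,
                members=tuple(sorted(symbols[idx])),
                effects=(delta_eff, ips_eff, es_eff),
            )
        )
    planted_mask = np.zeros(n, dtype=bool)
    for idx in planted_idx:
        planted_mask[idx] = True

    # --- detectability -----------------------------------------------------
    core = rng.random(n) < cfg.core_fraction
    core |= planted_mask
    lo, hi = cfg.peripheral_detect_range
    detect_p = np.where(core, 1.0, rng.uniform(lo, hi, n))

    true_by_comparison = {"delta": t_ie, "ips": t_ih, "es": t_eh}

    # --- technical replicate pairs and their integrated profiles -----------
    technical_pairs: dict[str, tuple[ProteinRatioProfile, ProteinRatioProfile]] = {}
    eight: dict[str, ProteinRatioProfile] = {}
    merge_cfg = IntegrationConfig(conflict_threshold=cfg.conflict_threshold)
    for role in EIGHT_ROLES:
        truth_values = true_by_comparison[_ROLE_COMPARISON[role]]
        detected = rng.random(n) < detect_p
        shared_idx = np.flatnonzero(detected)
        outside = np.flatnonzero(~detected)
        r = cfg.replicate_overlap
        n_extra = int(round(len(shared_idx) * (1.0 - r) / r))
        n_extra = min(n_extra, len(outside) // 2)
        extra = rng.choice(outside, size=2 * n_extra, replace=False)
        extra_a, extra_b = extra[:n_extra], extra[n_extra:]

        values_a: dict[str, float] = {}
        values_b: dict[str, float] = {}
        for idx_arr, values in ((np.concatenate([shared_idx, extra_a]), values_a),
                                (np.concatenate([shared_idx, extra_b]), values_b)):
            noise = rng.normal(0.0, cfg.noise_sd, len(idx_arr)) if cfg.noise_sd > 0 else 0.0
            vals = truth_values[idx_arr] + noise
            for j, i in enumerate(idx_arr):
                values[symbols[i]] = float(vals[j])

        # conflict injection: shared non-planted proteins forced into the
        # removal regime (opposite signs, linear fold changes >threshold apart)
        eligible = shared_idx[~planted_mask[shared_idx]]
        n_conflicts = rng.binomial(len(eligible), cfg.conflict_rate)
        if n_conflicts > 0:
            chosen = rng.choice(eligible, size=n_conflicts, replace=False)
            flip_a = rng.random(n_conflicts) < 0.5
            # magnitude > log2(threshold + 1) guarantees the fold-change gap
            big = np.log2(cfg.conflict_threshold + 1.0) + 0.2
            for j, i in enumerate(chosen):
                s = symbols[i]
                pos_mag = max(abs(values_a[s]), big)
                neg_mag = max(abs(values_b[s]), 0.05)
                if flip_a[j]:
                    values_a[s], values_b[s] = pos_mag, -neg_mag
                else:
                    values_a[s], values_b[s] = -neg_mag, pos_mag

        run_a = _profile_from_values(f"{role}.runA", list(values_a), values_a)
        run_b = _profile_from_values(f"{role}.runB", list(values_b), values_b)
        technical_pairs[role] = (run_a, run_b)
        merged, _ = merge_technical_replicates(run_a, run_b, merge_cfg, name=role)
        eight[role] = merged

    # --- gene sets: planted + random null sets -----------------------------
    sets: dict[str, frozenset[str]] = {
        t.name: frozenset(t.members) for t in truths
    }
    lo_s, hi_s = cfg.set_size_range
    for k in range(cfg.n_null_sets):
        size = int(rng.integers(lo_s, hi_s + 1))
        members = rng.choice(symbols, size=size, replace=False)
        sets[f"NULL_SET_{k:03d}"] = frozenset(members.tolist())
    gene_sets = GeneSetCollection(sets=sets, source="synthetic")

    # --- interaction edge list: planted sets form high-confidence modules --
    edges = ScoredEdgeList()
    for t in truths:
        members = list(t.members)
        for a, b in zip(members, members[1:] + members[:1]):  # ring
            edges.add(a, b, float(rng.uniform(0.6, 0.95)))
        n_chords = max(1, len(members) // 3)
        for _ in range(n_chords):
            a, b = rng.choice(members, size=2, replace=False)
            edges.add(a, b, float(rng.uniform(0.6, 0.95)))
    for _ in range(cfg.n_background_edges):
        a, b = rng.choice(symbols, size=2, replace=False)
        edges.add(a, b, float(rng.uniform(0.05, 0.95)))

    true_profiles = {
        name: _profile_from_values(name, symbols.tolist(), dict(zip(symbols, vals)))
        for name, vals in (
            ("true_delta", t_ie),
            ("true_ips", t_ih),
            ("true_es", t_eh),
        )
    }
    return SyntheticDataset(
        eight=eight,
        technical_pairs=technical_pairs,
        gene_sets=gene_sets,
        edges=edges,
        truth=SyntheticTruth(patterns=tuple(truths)),
        true_profiles=true_profiles,
    )


def small_config(seed: int = 0) -> SyntheticConfig:
    """A tiny, exhaustive-permutation-friendly configuration (universe 60)."""
    return SyntheticConfig(
        n_proteins=60,
        replicate_overlap=0.9,
        noise_sd=0.1,
        conflict_rate=0.05,
        n_null_sets=4,
        set_size_range=(5, 8),
        planted=(
            PlantedPattern(
                "PLANTED_INCOMPLETE_REPRESSION", INCOMPLETE_REPRESSION, size=6
            ),
            PlantedPattern(
                "PLANTED_INCOMPLETE_ACTIVATION", INCOMPLETE_ACTIVATION, size=6
            ),
        ),
        core_fraction=1.0,
        n_background_edges=60,
        rng_seed=seed,
    )


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> None:
    """Write a deterministic fixture set: a small and a full-scale dataset.

    ``small/`` uses a 60-protein universe so exhaustive permutation is
    feasible; ``full/`` uses the default configuration.  Each directory
    contains the eight integrated profiles, the technical-replicate run
    files, the gene sets (GMT), the edge list and the ground truth
    (``truth.json``).  Repeated runs with the same seed are byte-identical.
    """
    out_dir = Path(out_dir)
    configs = {
        "small": small_config(seed),
        "full": SyntheticConfig(rng_seed=seed),
    }
    for label, cfg in configs.items():
        target = out_dir / label
        target.mkdir(parents=True, exist_ok=True)
        data = generate(cfg)
        for role, profile in data.eight.items():
            write_profile(profile, target / f"{role}.tsv")
        for role, (run_a, run_b) in data.technical_pairs.items():
            write_profile(run_a, target / f"{role}.runA.tsv")
            write_profile(run_b, target / f"{role}.runB.tsv")
        write_gmt(data.gene_sets, target / "gene_sets.gmt")
        write_edge_list(data.edges, target / "edges.tsv")
        data.truth.to_json(target / "truth.json")
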
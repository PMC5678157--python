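"""Replicate merging and profile integration.

Two kinds of merges occur in the workflow:

* **technical** — two mass-spectrometry runs of the same sample.  Proteins
  quantified in both runs are kept; a protein whose two log2 ratios point in
  strictly opposite regulation directions *and* whose linear fold changes
  differ by more than a threshold (default 5) is removed as irreconcilable;
  every other shared protein gets the arithmetic mean of its two log2
  ratios (the geometric mean on the linear ratio scale).

* **biological** — profiles of two different cell lines for the same kind
  of comparison.  Strict intersection plus log2-ratio averaging; no
  conflict removal.

Eight per-cell-line comparison profiles (two pluripotent-vs-fibroblast pairs
and four cross comparisons) are folded into the three analysis profiles by
:func:`build_three_profiles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from pathtriad.profile_io import ProteinRatioProfile, ProteinRecord


@dataclass(frozen=True)
class IntegrationConfig:
    """Parameters of the technical-replicate conflict rule.

    ``conflict_threshold`` is on the **linear fold-change** scale: a shared
    protein is removed when its two ratios disagree in sign (log2 scale) and
    ``|2**r1 - 2**r2| > conflict_threshold``.
    """

    conflict_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.conflict_threshold <= 0:
            raise ValueError("conflict_threshold must be positive")


@dataclass
class IntegrationReport:
    """Accounting of one merge: input sizes, intersection, removals."""

    n_input_a: int
    n_input_b: int
    n_intersection: int
    removed_conflicts: list[str] = field(default_factory=list)
    n_output: int = 0


def is_conflict(r1: float, r2: float, threshold: float = 5.0) -> bool:
    """The replicate-conflict predicate.

    True iff the two log2 ratios have strictly opposite signs (a ratio of
    exactly 0 counts as neither direction) and the linear fold changes
    differ by more than ``threshold``.
    """
    if r1 * r2 >= 0:
        return False
    return abs(2.0 ** r1 - 2.0 ** r2) > threshold


def _merged_record(a: ProteinRecord, b: ProteinRecord) -> ProteinRecord:
    mean = (a.log2_ratio + b.log2_ratio) / 2.0
    return ProteinRecord(a.protein_id, a.gene_symbol, mean)


def merge_technical_replicates(
    a: ProteinRatioProfile,
    b: ProteinRatioProfile,
    cfg: IntegrationConfig | None = None,
    name: str | None = None,
    union: bool = False,
) -> tuple[ProteinRatioProfile, IntegrationReport]:
    """Merge two MS-run profiles of one sample.

    Shared proteins passing the conflict predicate are removed; retained
    shared proteins get the mean log2 ratio.  By default proteins quantified
    in only one run are dropped (strict intersection); ``union=True`` keeps
    them with their single observed value.
    """
    cfg = cfg or IntegrationConfig()
    shared = a.symbols & b.symbols
    if not shared:
        raise ValueError(
            f"profiles {a.name!r} and {b.name!r} share no proteins; check that "
            "both are keyed in the same identifier namespace"
        )
    removed: list[str] = []
    records: dict[str, ProteinRecord] = {}
    for symbol in sorted(shared):
        ra, rb = a.records[symbol], b.records[symbol]
        if is_conflict(ra.log2_ratio, rb.log2_ratio, cfg.conflict_threshold):
            removed.append(symbol)
        else:
            records[symbol] = _merged_record(ra, rb)
    if union:
        for profile in (a, b):
            for symbol in profile.symbols - shared:
                records[symbol] = profile.records[symbol]
    report = IntegrationReport(
        n_input_a=len(a),
        n_input_b=len(b),
        n_intersection=len(shared),
        removed_conflicts=removed,
        n_output=len(records),
    )
    merged = ProteinRatioProfile(name=name or f"{a.name}+{b.name}", records=records)
    return merged, report


def merge_biological(
    a: ProteinRatioProfile,
    b: ProteinRatioProfile,
    name: str | None = None,
) -> tuple[ProteinRatioProfile, IntegrationReport]:
    """Merge profiles of two cell lines: intersection + log2-ratio mean."""
    shared = a.symbols & b.symbols
    if not shared:
        raise ValueError(
            f"profiles {a.name!r} and {b.name!r} share no proteins; check that "
            "both are keyed in the same identifier namespace"
        )
    records = {
        symbol: _merged_record(a.records[symbol], b.records[symbol])
        for symbol in sorted(shared)
    }
    report = IntegrationReport(
        n_input_a=len(a),
        n_input_b=len(b),
        n_intersection=len(shared),
        removed_conflicts=[],
        n_output=len(records),
    )
    merged = ProteinRatioProfile(name=name or f"{a.name}+{b.name}", records=records)
    return merged, report


#: Roles of the eight input profiles.  ips1/ips2 are the two induced
#: pluripotent lines, es1/es2 the two embryonic lines, hff the shared
#: somatic precursor.
EIGHT_ROLES = (
    "ips1_vs_hff",
    "ips2_vs_hff",
    "es1_vs_hff",
    "es2_vs_hff",
    "ips1_vs_es1",
    "ips2_vs_es1",
    "ips1_vs_es2",
    "ips2_vs_es2",
)

#: Canonical names of the three analysis profiles.
DELTA, IPS_HFF, ES_HFF = "hiPSCs/hESCs", "hiPSCs/HFF", "hESCs/HFF"


def build_three_profiles(
    eight: Mapping[str, ProteinRatioProfile],
) -> tuple[dict[str, ProteinRatioProfile], dict[str, IntegrationReport]]:
    """Fold the eight comparison profiles into the three analysis profiles.

    The merging tree is fixed:

    * ``hiPSCs/HFF``  = biological merge of the two iPS-vs-fibroblast
      profiles;
    * ``hESCs/HFF``   = biological merge of the two ES-vs-fibroblast
      profiles;
    * ``hiPSCs/hESCs`` = two-stage: first merge the two iPS lines within
      each ES line (giving the ``hiPSCs/es1`` and ``hiPSCs/es2``
      intermediates), then merge across the two ES lines.

    Returns the three profiles keyed by canonical name plus the merge
    reports (including the two intermediates).
    """
    missing = [r for r in EIGHT_ROLES if r not in eight]
    extra = [k for k in eight if k not in EIGHT_ROLES]
    if missing or extra:
        raise ValueError(
            f"build_three_profiles needs exactly the roles {list(EIGHT_ROLES)}; "
            f"missing {missing}, unexpected {extra}"
        )
    reports: dict[str, IntegrationReport] = {}
    ips_hff, reports[IPS_HFF] = merge_biological(
        eight["ips1_vs_hff"], eight["ips2_vs_hff"], name=IPS_HFF
    )
    es_hff, reports[ES_HFF] = merge_biological(
        eight["es1_vs_hff"], eight["es2_vs_hff"], name=ES_HFF
    )
    ips_es1, reports["hiPSCs/es1"] = merge_biological(
        eight["ips1_vs_es1"], eight["ips2_vs_es1"], name="hiPSCs/es1"
    )
    ips_es2, reports["hiPSCs/es2"] = merge_biological(
        eight["ips1_vs_es2"], eight["ips2_vs_es2"], name="hiPSCs/es2"
    )
    delta, reports[DELTA] = merge_biological(ips_es1, ips_es2, name=DELTA)
    profiles = {IPS_HFF: ips_hff, ES_HFF: es_hff, DELTA: delta}
    return profiles, reports
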
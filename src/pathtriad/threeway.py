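"""Three-way cross-comparison of pathway regulation directions.

Three comparison profiles are involved: the pluripotent-vs-pluripotent
"delta" profile (hiPSCs/hESCs) and the two pluripotent-vs-somatic profiles
(hiPSCs/HFF and hESCs/HFF).  Each pathway gets a direction in each profile:

* ``UP`` / ``DOWN`` — tested and significant, sign of the enrichment score;
* ``NS`` — tested but not significant (FDR above threshold);
* ``NT`` — not tested (mapped protein count outside the size window).

The category of a pathway is a pure function of its direction triple.  The
biologically central patterns describe regulations that reprogramming did
not complete: a pathway repressed in both pluripotent cell types relative
to the somatic precursor yet still higher in the induced cells than in the
embryonic ones is *incompletely repressed*; the mirror image is
*incompletely activated*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from pathtriad.enrichment import EnrichmentResult
from pathtriad.profile_io import ProteinRatioProfile

UP, DOWN, NS, NT = "UP", "DOWN", "NS", "NT"
DIRECTIONS = (UP, DOWN, NS, NT)

INCOMPLETE_REPRESSION = "incomplete_repression"
INCOMPLETE_ACTIVATION = "incomplete_activation"
COMMON_UP = "common_up"
COMMON_DOWN = "common_down"
IPS_SPECIFIC = "ips_specific"
ES_SPECIFIC = "es_specific"
DELTA_ONLY = "delta_only"
UNINFORMATIVE = "uninformative"

CATEGORIES = (
    INCOMPLETE_REPRESSION,
    INCOMPLETE_ACTIVATION,
    COMMON_UP,
    COMMON_DOWN,
    IPS_SPECIFIC,
    ES_SPECIFIC,
    DELTA_ONLY,
    UNINFORMATIVE,
)

#: Strict sign pattern (delta, ips-vs-somatic, es-vs-somatic) that a
#: discriminating protein's log2 ratios must satisfy per category.
_SIGN_PATTERNS = {
    INCOMPLETE_REPRESSION: (1, -1, -1),
    INCOMPLETE_ACTIVATION: (-1, 1, 1),
}


def _significant(direction: str) -> bool:
    return direction in (UP, DOWN)


@dataclass(frozen=True)
class PathwayDirectionTriple:
    """Directions of one pathway across the three profiles.

    ``d_delta`` is the hiPSCs/hESCs direction, ``d_ips`` the hiPSCs/HFF
    one, ``d_es`` the hESCs/HFF one.  Mapped protein counts are kept so a
    reader can judge near-threshold ``NT`` calls (a pathway with 18–19
    mapped proteins just misses the default size window).
    """

    pathway: str
    d_delta: str
    d_ips: str
    d_es: str
    n_delta: int = 0
    n_ips: int = 0
    n_es: int = 0

    def __post_init__(self) -> None:
        for d in (self.d_delta, self.d_ips, self.d_es):
            if d not in DIRECTIONS:
                raise ValueError(f"direction must be one of {DIRECTIONS}, got {d!r}")


@dataclass(frozen=True)
class ThreeWayCall:
    """A pathway's direction triple plus its assigned category."""

    pathway: str
    category: str
    triple: PathwayDirectionTriple


def classify_pathway(triple: PathwayDirectionTriple) -> str:
    """Assign the regulation category of a direction triple (total function).

    Truth table, first match wins:

    1. ``(UP, DOWN, DOWN)`` → incomplete repression;
    2. ``(DOWN, UP, UP)`` → incomplete activation;
    3. both vs-somatic directions significant and equal with a
       non-significant delta → common up / common down;
    4. exactly one vs-somatic comparison significant: if the delta is
       significant in the *same* direction the signal is attributed to the
       delta profile (``delta_only``); otherwise the call is specific to
       that pluripotent line (``ips_specific`` / ``es_specific``);
    5. significant only in the delta profile → ``delta_only``;
    6. anything else → ``uninformative``.
    """
    d, i, e = triple.d_delta, triple.d_ips, triple.d_es
    if (d, i, e) == (UP, DOWN, DOWN):
        return INCOMPLETE_REPRESSION
    if (d, i, e) == (DOWN, UP, UP):
        return INCOMPLETE_ACTIVATION
    if _significant(i) and _significant(e):
        if i != e or _significant(d):
            return UNINFORMATIVE
        return COMMON_UP if i == UP else COMMON_DOWN
    if _significant(i) != _significant(e):
        hff_dir = i if _significant(i) else e
        if _significant(d) and d == hff_dir:
            return DELTA_ONLY
        return IPS_SPECIFIC if _significant(i) else ES_SPECIFIC
    if _significant(d):
        return DELTA_ONLY
    return UNINFORMATIVE


def _direction_of(result: EnrichmentResult | None) -> tuple[str, int]:
    if result is None:
        return NT, 0
    if not result.tested:
        return NT, result.mapped_n
    if result.significant:
        return result.direction, result.mapped_n
    return NS, result.mapped_n


_CATEGORY_ORDER = {c: k for k, c in enumerate(CATEGORIES)}


def build_three_way_table(
    r_delta: Sequence[EnrichmentResult],
    r_ips: Sequence[EnrichmentResult],
    r_es: Sequence[EnrichmentResult],
) -> list[ThreeWayCall]:
    """Cross-reference three enrichment runs into three-way calls.

    The three runs must come from the same gene-set collection (checked via
    the source tags).  One call is produced per pathway significant in at
    least one profile; incomplete-regulation calls are listed first.
    """
    sources = {
        r.source for results in (r_delta, r_ips, r_es) for r in results
    }
    if len(sources) > 1:
        raise ValueError(
            f"enrichment results come from different gene-set collections: {sorted(sources)}"
        )
    by_name = [
        {r.pathway: r for r in results} for results in (r_delta, r_ips, r_es)
    ]
    pathways = sorted(set().union(*[set(m) for m in by_name]))
    calls: list[ThreeWayCall] = []
    for pathway in pathways:
        results = [m.get(pathway) for m in by_name]
        (dd, nd), (di, ni), (de, ne) = (_direction_of(r) for r in results)
        if not any(_significant(x) for x in (dd, di, de)):
            continue
        triple = PathwayDirectionTriple(
            pathway=pathway,
            d_delta=dd,
            d_ips=di,
            d_es=de,
            n_delta=nd,
            n_ips=ni,
            n_es=ne,
        )
        calls.append(ThreeWayCall(pathway, classify_pathway(triple), triple))
    calls.sort(key=lambda c: (_CATEGORY_ORDER[c.category], c.pathway))
    return calls


def discriminating_proteins(
    call: ThreeWayCall,
    profiles: Mapping[str, ProteinRatioProfile],
    results: Mapping[str, EnrichmentResult | None],
) -> pd.DataFrame:
    """Leading-edge proteins whose ratio signs match an incomplete pattern.

    ``profiles`` and ``results`` are keyed ``"delta"`` / ``"ips"`` /
    ``"es"`` (results may be ``None`` where the pathway was untested).  A
    protein qualifies when it belongs to the union of the pathway's leading
    edges, is quantified in all three profiles, and its three log2 ratios
    carry the strict sign pattern of the category — positive in the delta
    profile and negative in both vs-somatic profiles for incomplete
    repression, the mirror for incomplete activation.  Zero ratios never
    qualify.

    Returns a DataFrame with columns ``gene_symbol``, ``delta``, ``ips``,
    ``es`` sorted by symbol.
    """
    if call.category not in _SIGN_PATTERNS:
        raise ValueError(
            f"discriminating proteins are defined only for incomplete categories, "
            f"got {call.category!r}"
        )
    pattern = _SIGN_PATTERNS[call.category]
    keys = ("delta", "ips", "es")
    missing = [k for k in keys if k not in profiles]
    if missing:
        raise ValueError(f"profiles mapping lacks {missing}")
    leading: set[str] = set()
    for k in keys:
        result = results.get(k)
        if result is not None:
            leading.update(result.leading_edge)
    rows = []
    for symbol in sorted(leading):
        if not all(symbol in profiles[k] for k in keys):
            continue
        values = [profiles[k].ratio(symbol) for k in keys]
        if all(v * s > 0 for v, s in zip(values, pattern)):
            rows.append(
                {
                    "gene_symbol": symbol,
                    "delta": values[0],
                    "ips": values[1],
                    "es": values[2],
                }
            )
    return pd.DataFrame(rows, columns=["gene_symbol", "delta", "ips", "es"])


def calls_to_frame(calls: Sequence[ThreeWayCall]) -> pd.DataFrame:
    """Tabular report: one row per call, direction triple and mapped counts."""
    rows = []
    for c in calls:
        t = c.triple
        rows.append(
            {
                "pathway": c.pathway,
                "category": c.category,
                "delta": t.d_delta,
                "ips_vs_somatic": t.d_ips,
                "es_vs_somatic": t.d_es,
                "n_delta": t.n_delta,
                "n_ips": t.n_ips,
                "n_es": t.n_es,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "category",
            "delta",
            "ips_vs_somatic",
            "es_vs_somatic",
            "n_delta",
            "n_ips",
            "n_es",
        ],
    )
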
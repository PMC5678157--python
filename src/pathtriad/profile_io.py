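"""Reading and writing of protein ratio profiles, gene-set collections (GMT).

A *ratio profile* is the atomic dataset of the pipeline: one log2 expression
ratio per protein for a single comparison of two cell types (for instance
hiPSCs versus their precursor fibroblasts).  Profiles are keyed by uppercase
gene symbol so they can be matched against MSigDB-style gene sets; the raw
protein accession (the mass-spectrometry identifier, e.g. an IPI accession)
is carried along as metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Accepted header spellings for each logical profile column (lower-cased).
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "protein_id": ("protein_id", "accession", "protein", "ipi", "id"),
    "gene_symbol": ("gene_symbol", "symbol", "gene", "gene_name"),
    "log2_ratio": ("log2_ratio", "log2ratio", "log2", "log2_fc"),
    "ratio": ("ratio", "expression_ratio", "fold_change", "fc"),
}


class ProfileFormatError(ValueError):
    """A tabular input file does not match the expected layout."""


@dataclass(frozen=True)
class ProteinRecord:
    """One quantified protein: accession, gene symbol and log2 ratio."""

    protein_id: str
    gene_symbol: str
    log2_ratio: float

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if not math.isfinite(self.log2_ratio):
            raise ValueError(
                f"log2_ratio for {self.gene_symbol!r} is not finite: {self.log2_ratio}"
            )


@dataclass
class ProteinRatioProfile:
    """A named comparison profile: gene symbol -> :class:`ProteinRecord`.

    ``name`` labels the comparison as numerator/denominator
    (e.g. ``"hiPSCs/HFF"``).  Keys are unique by construction.
    """

    name: str
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.records

    @property
    def symbols(self) -> set[str]:
        return set(self.records)

    def ratio(self, symbol: str) -> float:
        return self.records[symbol].log2_ratio

    def as_series(self) -> pd.Series:
        """Log2 ratios as a pandas Series indexed by gene symbol (sorted)."""
        symbols = sorted(self.records)
        values = [self.records[s].log2_ratio for s in symbols]
        return pd.Series(values, index=symbols, name=self.name, dtype=float)

    def negated(self, name: str | None = None) -> "ProteinRatioProfile":
        """The reciprocal comparison: every log2 ratio negated.

        Swapping numerator and denominator of an expression ratio negates
        its log2; this is how an hESCs/HFF profile is turned into the
        HFF/hESCs axis of a scatter plot.
        """
        if name is None:
            parts = self.name.split("/")
            name = "/".join(reversed(parts)) if len(parts) == 2 else f"neg({self.name})"
        flipped = {
            sym: replace(rec, log2_ratio=-rec.log2_ratio)
            for sym, rec in self.records.items()
        }
        return ProteinRatioProfile(name=name, records=flipped)

    @classmethod
    def from_pairs(
        cls,
        name: str,
        pairs: Iterable[tuple[str, float]],
        protein_ids: Mapping[str, str] | None = None,
    ) -> "ProteinRatioProfile":
        """Build a profile from ``(gene_symbol, log2_ratio)`` pairs."""
        records: dict[str, ProteinRecord] = {}
        for symbol, value in pairs:
            symbol = _normalize_symbol(symbol)
            pid = protein_ids.get(symbol, symbol) if protein_ids else symbol
            records[symbol] = ProteinRecord(pid, symbol, float(value))
        return cls(name=name, records=records)


@dataclass
class GeneSetCollection:
    """Named pathways, each a set of uppercase gene symbols."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for pathway, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {pathway!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _resolve_columns(
    columns: Iterable[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map logical column roles onto the actual header names.

    ``column_map`` overrides the built-in aliases, e.g.
    ``{"gene_symbol": "Gene names"}`` for a supplementary-table layout.
    """
    lower = {str(c).strip().lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for role, aliases in _COLUMN_ALIASES.items():
        if column_map and role in column_map:
            wanted = column_map[role].strip().lower()
            if wanted in lower:
                resolved[role] = lower[wanted]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[role] = lower[alias]
                break
    return resolved


def read_profile(
    path: str | Path,
    ratio_scale: str = "log2",
    name: str | None = None,
    column_map: Mapping[str, str] | None = None,
    key_on: str = "symbol",
) -> ProteinRatioProfile:
    """Read a tab-separated ratio profile.

    Parameters
    ----------
    path:
        TSV file with a header; must contain an identifier column, a gene
        symbol column, and a ratio column (see ``column_map`` for
        non-standard headers).
    ratio_scale:
        ``"log2"`` if the ratio column already holds log2 ratios,
        ``"linear"`` if it holds raw expression ratios (converted with
        ``log2``; non-positive values are rejected).
    name:
        Profile label; defaults to the file stem.
    column_map:
        Optional mapping from the logical roles ``protein_id`` /
        ``gene_symbol`` / ``log2_ratio`` / ``ratio`` to actual header names,
        for permissive reading of third-party table layouts.
    key_on:
        ``"symbol"`` (default) keys records by gene symbol; ``"accession"``
        keys them by protein identifier instead (the symbol is still
        normalized and carried in each record).

    Duplicate keys are resolved by keeping the record with the largest
    absolute log2 ratio; a warning is logged.
    """
    if ratio_scale not in ("linear", "log2"):
        raise ValueError(f"ratio_scale must be 'linear' or 'log2', got {ratio_scale!r}")
    if key_on not in ("symbol", "accession"):
        raise ValueError(f"key_on must be 'symbol' or 'accession', got {key_on!r}")
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    resolved = _resolve_columns(frame.columns, column_map)
    ratio_role = "log2_ratio" if ratio_scale == "log2" else "ratio"
    missing = [
        role
        for role in ("protein_id", "gene_symbol")
        if role not in resolved
    ]
    if ratio_role not in resolved:
        # A plain 'ratio' header is acceptable for log2 input and vice versa
        # only through an explicit column_map; otherwise fail loudly.
        missing.append(ratio_role)
    if missing:
        raise ProfileFormatError(
            f"{path}: missing column(s) for {missing}; found {list(frame.columns)}"
        )

    records: dict[str, ProteinRecord] = {}
    pid_col = frame[resolved["protein_id"]]
    sym_col = frame[resolved["gene_symbol"]]
    val_col = frame[resolved[ratio_role]]
    for i in range(len(frame)):
        row_number = i + 2  # header is line 1
        pid = str(pid_col.iloc[i]).strip()
        symbol = _normalize_symbol(sym_col.iloc[i])
        try:
            value = float(val_col.iloc[i])
        except (TypeError, ValueError) as exc:
            raise ProfileFormatError(
                f"{path}, line {row_number}: unparsable ratio {val_col.iloc[i]!r}"
            ) from exc
        if ratio_scale == "linear":
            if value <= 0:
                raise ValueError(
                    f"{path}, line {row_number}: non-positive linear ratio {value}"
                    f" for {symbol!r}"
                )
            value = math.log2(value)
        record = ProteinRecord(pid, symbol, value)
        key = symbol if key_on == "symbol" else pid
        if key in records:
            kept = max(records[key], record, key=lambda r: abs(r.log2_ratio))
            logger.warning(
                "%s: duplicate key %r; keeping log2_ratio %.6g (largest magnitude)",
                path,
                key,
                kept.log2_ratio,
            )
            records[key] = kept
        else:
            records[key] = record
    return ProteinRatioProfile(name=name or path.stem, records=records)


def write_profile(profile: ProteinRatioProfile, path: str | Path) -> None:
    """Write a profile as TSV (columns protein_id, gene_symbol, log2_ratio).

    Floats are written with :func:`repr`, so a write/read round trip
    reproduces every log2 ratio bit-for-bit.
    """
    path = Path(path)
    lines = ["protein_id\tgene_symbol\tlog2_ratio"]
    for symbol in sorted(profile.records):
        rec = profile.records[symbol]
        lines.append(f"{rec.protein_id}\t{rec.gene_symbol}\t{rec.log2_ratio!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, then member symbols).

    Member symbols are uppercased; duplicates within a set collapse.  A
    duplicated set name is an error; an empty file yields an empty
    collection with a logged warning.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ProfileFormatError(
                    f"{path}, line {line_number}: GMT line needs >=3 tab-separated"
                    f" fields, got {len(fields)}"
                )
            pathway = fields[0].strip()
            if pathway in sets:
                raise ProfileFormatError(
                    f"{path}, line {line_number}: duplicate set name {pathway!r}"
                )
            members = frozenset(
                _normalize_symbol(s) for s in fields[2:] if s.strip()
            )
            if not members:
                raise ProfileFormatError(
                    f"{path}, line {line_number}: set {pathway!r} has no members"
                )
            sets[pathway] = members
    if not sets:
        logger.warning("%s: empty gene-set file", path)
    return GeneSetCollection(sets=sets, source=source or path.stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a gene-set collection in GMT format (members sorted)."""
    path = Path(path)
    lines = []
    for pathway in sorted(collection.sets):
        members = "\t".join(sorted(collection.sets[pathway]))
        lines.append(f"{pathway}\t{collection.source}\t{members}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
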
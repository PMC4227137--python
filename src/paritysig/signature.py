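"""Gene signatures: named gene lists with a direction and a training fold change.

A signature is the unit of transfer in this package: it is discovered in a
training cohort (e.g. by SAM differential expression), written to disk as TSV
or GMT, and later aligned to an independent expression matrix for enrichment
testing or correlation-template classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import SignatureMatchError

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class SignatureEntry:
    """One signature gene with its direction and optional linear fold change."""

    gene: str
    direction: str = "up"
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r} for gene {self.gene!r}")
        if self.fold_change is not None:
            fc = float(self.fold_change)
            if not fc > 0:
                raise ValueError(f"fold change must be positive, got {fc} for {self.gene!r}")
            # direction and fold change must not contradict each other; FC == 1
            # is compatible with either direction (degenerate effect).
            if (self.direction == "up" and fc < 1) or (self.direction == "down" and fc > 1):
                raise ValueError(
                    f"direction {self.direction!r} inconsistent with fold change {fc} "
                    f"for gene {self.gene!r}"
                )


@dataclass
class GeneSignature:
    """An ordered list of unique signature genes."""

    name: str
    entries: tuple[SignatureEntry, ...]

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        genes = [e.gene for e in self.entries]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate genes in signature {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def fold_changes(self) -> list[float | None]:
        return [e.fold_change for e in self.entries]

    def has_fold_changes(self) -> bool:
        return all(e.fold_change is not None for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "direction": [e.direction for e in self.entries],
                "fold_change": self.fold_changes,
            }
        )


def align_signature(
    sig: GeneSignature,
    matrix: pd.DataFrame,
    min_match_fraction: float = 0.5,
) -> tuple[GeneSignature, float]:
    """Restrict a signature to the genes present in an expression matrix.

    Matching is by gene symbol, case-insensitive, preserving signature order.
    The returned entries carry the matrix's spelling of each symbol so they can
    be used directly for row indexing.

    Returns the restricted signature and the match fraction (matched / total).
    Raises :class:`SignatureMatchError` when the fraction falls below
    ``min_match_fraction``.
    """
    if not matrix.index.is_unique:
        raise ValueError("expression matrix has duplicate gene ids; collapse probes first")
    if len(sig) == 0:
        raise ValueError(f"signature {sig.name!r} is empty")
    lookup: dict[str, str] = {}
    for g in matrix.index:
        lookup.setdefault(str(g).casefold(), str(g))
    matched: list[SignatureEntry] = []
    missing: list[str] = []
    for entry in sig.entries:
        hit = lookup.get(entry.gene.casefold())
        if hit is None:
            missing.append(entry.gene)
        else:
            matched.append(SignatureEntry(hit, entry.direction, entry.fold_change))
    fraction = len(matched) / len(sig)
    if fraction < min_match_fraction:
        raise SignatureMatchError(
            f"only {len(matched)}/{len(sig)} genes of signature {sig.name!r} found "
            f"(fraction {fraction:.2f} < floor {min_match_fraction}); "
            f"missing: {', '.join(missing[:20])}"
            + ("..." if len(missing) > 20 else "")
        )
    if missing:
        logger.info(
            "signature %s: %d/%d genes matched (%d missing)",
            sig.name, len(matched), len(sig), len(missing),
        )
    return GeneSignature(sig.name, tuple(matched)), fraction
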
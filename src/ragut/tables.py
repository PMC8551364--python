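"""Abundance tables and taxonomic lineages.

The universal currency of the pipeline is the :class:`AbundanceTable`, a
features × samples matrix of relative abundances (percent, 0–100, for
taxonomic tables) or nonnegative pathway/gene-family abundances, tagged with
the level it was measured at.  Taxonomic feature ids are full pipe-delimited
lineage strings in the MetaPhlAn convention (``k__...|p__...|...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "strain")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")
_PREFIX_TO_RANK = dict(zip(RANK_PREFIXES, RANK_ORDER))
_RANK_TO_PREFIX = dict(zip(RANK_ORDER, RANK_PREFIXES))

LEVELS = RANK_ORDER[:-1] + ("gene_family", "pathway")


class LineageError(ValueError):
    """Raised for malformed pipe-delimited lineage strings."""


@dataclass(frozen=True)
class Lineage:
    """Ordered rank→name mapping forming a contiguous prefix of the rank order."""

    ranks: tuple[tuple[str, str], ...]  # ((rank, name), ...) in canonical order

    @property
    def deepest_rank(self) -> str:
        return self.ranks[-1][0]

    def name(self, rank: str) -> str | None:
        for r, n in self.ranks:
            if r == rank:
                return n
        return None

    def prefix(self, rank: str) -> str:
        """Lineage string truncated at ``rank`` (inclusive)."""
        out = []
        for r, n in self.ranks:
            out.append(_RANK_TO_PREFIX[r] + n)
            if r == rank:
                return "|".join(out)
        raise LineageError(f"rank {rank!r} not present in lineage")

    def __str__(self) -> str:
        return "|".join(_RANK_TO_PREFIX[r] + n for r, n in self.ranks)


def parse_lineage(lineage: str) -> Lineage:
    """Parse a pipe-delimited, rank-prefixed lineage string.

    The ranks present must form a contiguous prefix of
    kingdom→phylum→class→order→family→genus→species(→strain) and every
    present rank must carry a non-empty name.
    """
    tokens = lineage.split("|")
    ranks: list[tuple[str, str]] = []
    for i, tok in enumerate(tokens):
        prefix = tok[:3]
        if prefix not in _PREFIX_TO_RANK:
            raise LineageError(f"unrecognised rank prefix in token {tok!r} of {lineage!r}")
        expected = RANK_PREFIXES[i]
        if prefix != expected:
            raise LineageError(
                f"rank prefixes out of order in {lineage!r}: "
                f"position {i} has {prefix!r}, expected {expected!r}"
            )
        name = tok[3:]
        if not name:
            raise LineageError(f"empty name for rank {prefix!r} in {lineage!r}")
        ranks.append((_PREFIX_TO_RANK[prefix], name))
    if not ranks:
        raise LineageError("empty lineage string")
    return Lineage(tuple(ranks))


def deepest_rank(lineage: str) -> str:
    """Deepest rank of a lineage string without full validation of names."""
    return parse_lineage(lineage).deepest_rank


@dataclass
class AbundanceTable:
    """Features × samples abundance matrix with a level tag.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with one column per sample.
    level:
        One of kingdom..species, gene_family or pathway.
    """

    data: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS and self.level != "strain":
            raise ValueError(f"unknown level {self.level!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("negative abundance values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[:, list(sample_ids)], self.level)

    def lineages(self) -> dict[str, Lineage]:
        """Parse every feature id as a lineage (taxonomic tables only)."""
        return {fid: parse_lineage(fid) for fid in self.data.index}


def extract_rank_table(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Aggregate a species-level table up to ``rank`` by summing species.

    Per-sample column sums are conserved exactly: every species contributes
    to exactly one ancestor at the requested rank.
    """
    if rank not in RANK_ORDER[:-1]:
        raise ValueError(f"unknown rank {rank!r}")
    source_idx = RANK_ORDER.index(table.level)
    target_idx = RANK_ORDER.index(rank)
    if target_idx >= source_idx:
        raise ValueError(f"rank {rank!r} is not above table level {table.level!r}")
    prefixes = [parse_lineage(fid).prefix(rank) for fid in table.data.index]
    grouped = table.data.groupby(pd.Index(prefixes, name=table.data.index.name)).sum()
    grouped = grouped.sort_index()
    return AbundanceTable(grouped, rank)
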
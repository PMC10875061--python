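"""Core domain containers.

The single source of truth is the :class:`AbundanceTable`, a samples x taxa
matrix of read counts. Taxonomic assignments and per-sample metadata are
carried separately and merged into the composition graph at build time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    IdentifierCollisionError,
    ValidationError,
)

#: The eight taxonomic ranks, shallowest first.
RANKS = (
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Sentinel marking an unassigned rank. Display layers may render it as
#: "unclassified"; it never matches a taxonomy query value.
UNASSIGNED = ""


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of absolute read counts.

    Rows are samples, columns taxa (OTUs/ASVs). Counts are non-negative;
    zero means the taxon was not observed in that sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise EmptyInputError("abundance table has no cells")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise IdentifierCollisionError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise IdentifierCollisionError(f"duplicate taxon ids: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance table cells must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        """Counts as an (n_samples, n_taxa) array."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def transpose(self) -> "AbundanceTable":
        return AbundanceTable(self.data.T.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class TaxonomyTable:
    """Per-taxon rank assignments.

    ``assignments`` maps a taxon id to one value per rank in :data:`RANKS`.
    Unassigned ranks carry the empty-string sentinel and obey the prefix
    property: once a rank is unassigned all deeper ranks are too.
    """

    assignments: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        cleaned = {}
        for taxon, ranks in self.assignments.items():
            ranks = tuple(str(r) if r is not None else UNASSIGNED for r in ranks)
            if len(ranks) > len(RANKS):
                raise ValidationError(
                    f"taxon {taxon!r}: {len(ranks)} rank values, "
                    f"at most {len(RANKS)} allowed"
                )
            ranks = ranks + (UNASSIGNED,) * (len(RANKS) - len(ranks))
            seen_unassigned = False
            for name, value in zip(RANKS, ranks):
                if value == UNASSIGNED:
                    seen_unassigned = True
                elif seen_unassigned:
                    raise ValidationError(
                        f"taxon {taxon!r}: rank {name!r} assigned below an "
                        "unassigned rank (prefix property violated)"
                    )
            cleaned[str(taxon)] = ranks
        self.assignments = cleaned

    def rank_value(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.assignments[taxon_id][RANKS.index(rank)]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.assignments


@dataclass
class SampleMetadata:
    """Per-sample key/value attributes plus an optional grouping variable."""

    records: dict[str, dict[str, object]]
    group_key: Optional[str] = None

    def __post_init__(self) -> None:
        self.records = {str(k): dict(v) for k, v in self.records.items()}
        if self.group_key is not None:
            missing = [
                s
                for s, attrs in self.records.items()
                if not str(attrs.get(self.group_key, "") or "").strip()
            ]
            if missing:
                raise ValidationError(
                    f"group key {self.group_key!r} missing or empty for "
                    f"samples: {missing}"
                )

    def group_of(self, sample_id: str) -> Optional[str]:
        if self.group_key is None:
            return None
        return str(self.records[sample_id][self.group_key])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix over labelled samples."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise IdentifierCollisionError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValidationError("distance matrix is not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if (self.values < 0).any():
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])
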
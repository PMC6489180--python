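"""Core in-memory containers shared across the package.

The method works on *layered* gene nodes: the same gene symbol can appear
once in the expression layer and once in the copy-number layer, and the
two are distinct vertices of the integrated graph and distinct members of
a pathway's differential-gene set.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

GOOD = "GOOD"
POOR = "POOR"


class LayerKind(str, enum.Enum):
    """What kind of measurements an omics matrix holds."""

    MICROARRAY = "MICROARRAY"     # continuous log-intensities
    RNASEQ_COUNTS = "RNASEQ_COUNTS"  # nonnegative integer counts
    CNA_CALLS = "CNA_CALLS"       # discrete calls in {-2,-1,0,1,2}


class Layer(str, enum.Enum):
    """Graph layer of a node. Sorting uses the string value, so CNA < EXPR."""

    CNA = "CNA"
    EXPR = "EXPR"


_CNA_VALID = frozenset({-2, -1, 0, 1, 2})


@dataclass
class OmicsMatrix:
    """One omics layer: gene x sample values plus the kind of the layer.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample ids
    as columns. Gene symbols and sample ids must be unique.
    """

    layer_kind: LayerKind
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene symbols: {dup}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if self.layer_kind is LayerKind.CNA_CALLS:
            finite = vals[np.isfinite(vals)]
            bad = ~np.isin(finite, list(_CNA_VALID))
            if bad.any():
                raise ValueError(
                    f"CNA calls must lie in {{-2,-1,0,1,2}}; found {sorted(set(finite[bad]))[:5]}"
                )
        elif self.layer_kind is LayerKind.RNASEQ_COUNTS:
            if np.nanmin(vals) < 0 if vals.size else False:
                raise ValueError("RNA-seq counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def graph_layer(self) -> Layer:
        return Layer.CNA if self.layer_kind is LayerKind.CNA_CALLS else Layer.EXPR

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.layer_kind, self.values.loc[:, list(samples)])


@dataclass
class SampleLabels:
    """Binary survival-group labels (GOOD / POOR) per sample id."""

    labels: pd.Series  # sample id -> GOOD | POOR

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        bad = set(self.labels.unique()) - {GOOD, POOR}
        if bad:
            raise ValueError(f"labels must be GOOD or POOR, found {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in labels")

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    def poor_mask(self, samples: Sequence[str]) -> np.ndarray:
        """Boolean array: True where the sample is in the POOR group."""
        return (self.labels.loc[list(samples)] == POOR).to_numpy()

    def subset(self, samples: Sequence[str]) -> "SampleLabels":
        return SampleLabels(self.labels.loc[list(samples)])

    def require_both_classes(self, min_per_class: int = 1) -> None:
        mask = self.poor_mask(self.samples)
        if mask.sum() < min_per_class or (~mask).sum() < min_per_class:
            raise ValueError(
                f"need at least {min_per_class} samples per class; "
                f"got {int((~mask).sum())} GOOD / {int(mask.sum())} POOR"
            )


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.id!r} has no members")


@dataclass
class PathwayCollection(Mapping[str, Pathway]):
    """Ordered mapping pathway id -> Pathway, GMT-style."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Pathway:
        return self.pathways[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def add(self, pathway: Pathway) -> None:
        if pathway.id in self.pathways:
            raise ValueError(f"duplicate pathway id {pathway.id!r}")
        self.pathways[pathway.id] = pathway

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self.pathways == other.pathways
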
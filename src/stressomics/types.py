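"""Core in-memory containers shared across the pipeline.

The pipeline moves data around as plain pandas DataFrames with documented
column contracts, wrapped in a handful of light dataclasses where extra
metadata (sample annotations, modality tags) must travel with the values.

Column contracts
----------------
DE result table (one contrast in one data set):
    ``feature_id, logFC, FC, t, P, Padj, contrast, dataset``
Enrichment result table:
    ``set_name, ES, NES, P, PFDR, method, comparison``
Sample metadata table (indexed by sample id):
    ``strain, tissue, group, batch``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidMatrixError

TRIAL_LENGTH_S = 150.0  # social-avoidance trial duration, seconds

CONTRASTS = ("susceptible-vs-control", "resilient-vs-control", "susceptible-vs-resilient")

GROUPS = ("control", "defeated")
PHENOTYPES = ("control", "susceptible", "resilient", "excluded")


@dataclass
class BehavioralRecord:
    """One mouse's behavioral measurements.

    Times are seconds spent in the interaction zone during the no-target
    (trial I) and target (trial II) trials of the social-avoidance test.
    """

    mouse_id: str
    strain: str
    group: str  # "control" | "defeated"
    t_iz_no_target: float
    t_iz_target: float
    weights: Sequence[float] | None = None  # grams per recorded day

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for t in (self.t_iz_no_target, self.t_iz_target):
            if not (0.0 <= t <= TRIAL_LENGTH_S):
                raise ValueError(f"interaction-zone time {t} outside [0, {TRIAL_LENGTH_S}] s")


@dataclass
class PhenotypeCall:
    """Susceptible/resilient/control label for one mouse."""

    mouse_id: str
    si_ratio: float  # percent scale
    outlier: bool
    label: str  # "control" | "susceptible" | "resilient" | "excluded"

    def __post_init__(self) -> None:
        if self.label not in PHENOTYPES:
            raise ValueError(f"label must be one of {PHENOTYPES}, got {self.label!r}")


@dataclass
class OmicsMatrix:
    """Features x samples values plus sample metadata and a modality tag.

    ``values`` rows are feature identifiers, columns are sample identifiers.
    ``meta`` is indexed by sample identifier and carries at least
    ``strain, tissue, group, batch``. Counts modalities ("mrna", "mirna")
    hold non-negative integers; "protein" holds log2 H/L ratios.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    modality: str  # "mrna" | "mirna" | "protein"

    COUNT_MODALITIES = ("mrna", "mirna")

    def __post_init__(self) -> None:
        self.values.index.name = "feature_id"
        self.values.columns.name = None
        self.meta.index.name = "sample_id"
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InvalidMatrixError(f"duplicate feature identifiers: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise InvalidMatrixError(f"samples absent from metadata: {missing}")
        if self.modality in self.COUNT_MODALITIES:
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise InvalidMatrixError("negative counts in a count modality")
            if not np.allclose(arr, np.round(arr)):
                raise InvalidMatrixError("non-integer counts in a count modality")

    @property
    def is_counts(self) -> bool:
        return self.modality in self.COUNT_MODALITIES

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        ids = list(sample_ids)
        return OmicsMatrix(self.values[ids], self.meta.loc[ids], self.modality)


@dataclass
class GeneSetCollection:
    """Named sets of feature identifiers with optional category labels."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            # dedup, preserving order
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class SignedRegulon:
    """An upstream regulator with signed target edges (+1 activating, -1 repressing)."""

    name: str
    targets: dict[str, int]

    def __post_init__(self) -> None:
        bad = {t: s for t, s in self.targets.items() if s not in (+1, -1)}
        if bad:
            raise ValueError(f"edge signs must be +1/-1, got {bad}")


def de_table(
    feature_ids: Sequence[str],
    logfc: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    padj: np.ndarray,
    contrast: str,
    dataset: str,
) -> pd.DataFrame:
    """Assemble a DE result table with the canonical column contract.

    FC is the signed linear fold change: 2**logFC for up-regulation,
    -2**|logFC| for down-regulation (the field's signed-FC convention).
    """
    logfc = np.asarray(logfc, dtype=float)
    fc = np.where(logfc >= 0, 2.0 ** logfc, -(2.0 ** np.abs(logfc)))
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "logFC": logfc,
            "FC": fc,
            "t": np.asarray(t, dtype=float),
            "P": np.asarray(p, dtype=float),
            "Padj": np.asarray(padj, dtype=float),
            "contrast": contrast,
            "dataset": dataset,
        }
    )


ContrastGrid = Mapping[tuple[str, str, str], pd.DataFrame]
"""Mapping (dataset, strain, contrast) -> DE or enrichment result table.

The canonical grid of the integrative analysis is 2 strains x 3 contrasts
x 2 omics layers = 12 comparisons.
"""
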
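"""Domain types for the driver-prioritization pipeline.

The central objects are :class:`QuantDataset` (one mass-spectrometry
dataset: a proteins x samples abundance matrix plus protein lengths and
sample conditions), :class:`SurvivalCohort` (patient time/event records
with per-protein expression), :class:`ComponentScore` (one ranking
component's per-protein metric values together with its ranking
direction), :class:`RankVector` (per-protein ranks 1..x for one
component) and :class:`CandidateReport` (the final integrated table).

Protein identity for cross-dataset matching is the gene symbol; the
accession is carried for provenance only.  All containers validate their
invariants on construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Sample conditions a quantification dataset may declare.
CONDITIONS = frozenset({"tumor", "normal", "cell_line", "ctc"})

#: Metric names and their fixed ranking directions.  ``lower_is_better``
#: metrics are ranked ascending (rank 1 = smallest value), the rest
#: descending (rank 1 = largest value).
METRIC_DIRECTIONS = {
    "abundance": "higher_is_better",
    "p_diff": "lower_is_better",
    "ratio": "higher_is_better",
    "abs_change": "higher_is_better",
    "p_logrank": "lower_is_better",
    "hazard_ratio": "higher_is_better",
}

#: Survival endpoints understood by the pipeline.
ENDPOINTS = frozenset({"OS", "DMFS"})


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, gene symbol and length in amino acids."""

    accession: str
    symbol: str
    length_aa: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if not self.symbol:
            raise ValidationError(f"{self.accession}: symbol must be non-empty")
        if int(self.length_aa) != self.length_aa or self.length_aa < 1:
            raise ValidationError(
                f"{self.accession}: length_aa must be an integer >= 1, "
                f"got {self.length_aa!r}"
            )


@dataclass
class QuantDataset:
    """One quantified MS dataset.

    Parameters
    ----------
    dataset_id:
        Identifier used in component ids and provenance.
    proteins:
        DataFrame indexed by gene symbol with columns ``accession`` and
        ``length_aa``.  Symbols are unique (duplicate symbols are collapsed
        upstream by the readers).
    abundance:
        DataFrame of non-negative abundances (spectral/PSM counts or
        intensities), indexed like ``proteins``, one column per sample;
        NaN marks a missing (undetected) cell.
    conditions:
        Series mapping sample_id -> condition, one entry per abundance
        column, values drawn from :data:`CONDITIONS`.
    """

    dataset_id: str
    proteins: pd.DataFrame
    abundance: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.abundance.shape[1] < 1:
            raise ValidationError(f"{self.dataset_id}: at least one sample required")
        if not self.proteins.index.equals(self.abundance.index):
            raise ValidationError(
                f"{self.dataset_id}: protein table and abundance matrix disagree"
            )
        if self.proteins.index.has_duplicates:
            dupes = self.proteins.index[self.proteins.index.duplicated()].tolist()
            raise ValidationError(f"{self.dataset_id}: duplicate symbols {dupes}")
        if self.proteins["accession"].duplicated().any():
            raise ValidationError(f"{self.dataset_id}: duplicate accessions")
        missing_cols = {"accession", "length_aa"} - set(self.proteins.columns)
        if missing_cols:
            raise ValidationError(f"{self.dataset_id}: missing columns {missing_cols}")
        if (self.proteins["length_aa"] < 1).any():
            raise ValidationError(f"{self.dataset_id}: length_aa must be >= 1")
        if set(self.abundance.columns) != set(self.conditions.index):
            raise ValidationError(
                f"{self.dataset_id}: sample sheet does not cover the matrix columns"
            )
        bad = set(self.conditions) - CONDITIONS
        if bad:
            raise ValidationError(f"{self.dataset_id}: unknown conditions {bad}")
        values = self.abundance.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValidationError(f"{self.dataset_id}: negative abundance")

    @property
    def symbols(self) -> list[str]:
        return list(self.proteins.index)

    def samples_for(self, conditions: set[str]) -> list[str]:
        """Sample ids whose condition is in ``conditions``, matrix order."""
        keep = {s for s, c in self.conditions.items() if c in conditions}
        return [s for s in self.abundance.columns if s in keep]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (the candidate universe)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SurvivalCohort:
    """Patient survival records with per-protein expression.

    ``data`` is indexed by patient_id and holds ``time`` (positive reals,
    consistent units), ``event`` (0 censored / 1 event) and one column per
    protein symbol (expression, NaN = missing).
    """

    cohort_id: str
    endpoint: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(
                f"{self.cohort_id}: endpoint must be one of {sorted(ENDPOINTS)}"
            )
        if self.data.index.has_duplicates:
            raise ValidationError(f"{self.cohort_id}: duplicate patient_id")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"{self.cohort_id}: missing column {col!r}")
        if (self.data["time"] <= 0).any():
            raise ValidationError(f"{self.cohort_id}: time must be > 0")
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError(f"{self.cohort_id}: event values must be 0 or 1")

    @property
    def proteins(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def expression(self, symbol: str) -> pd.Series:
        return self.data[symbol]


@dataclass
class ComponentScore:
    """Per-protein metric values for one ranking component.

    ``values`` maps gene symbol -> metric value (NaN allowed = protein not
    scoreable in this component).  The ranking ``direction`` is fixed by
    ``metric_name`` via :data:`METRIC_DIRECTIONS`.
    """

    component_id: str
    dataset_id: str
    metric_name: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_DIRECTIONS:
            raise ValidationError(f"unknown metric {self.metric_name!r}")
        finite = self.values.dropna()
        if np.isinf(finite.to_numpy(dtype=float)).any():
            raise ValidationError(
                f"{self.component_id}: metric values must be finite where present"
            )

    @property
    def direction(self) -> str:
        return METRIC_DIRECTIONS[self.metric_name]


@dataclass
class RankVector:
    """Ranks 1..x for one component; average ranks on ties.

    The sum of ranks is always x(x+1)/2, the signature of average-tie
    ranking over x items.
    """

    component_id: str
    ranks: pd.Series
    x: int

    def __post_init__(self) -> None:
        if len(self.ranks) != self.x:
            raise ValidationError(
                f"{self.component_id}: {len(self.ranks)} ranks but x={self.x}"
            )
        if self.x == 0:
            raise ValidationError(f"{self.component_id}: empty rank vector")
        r = self.ranks.to_numpy(dtype=float)
        if r.min() < 1 or r.max() > self.x:
            raise ValidationError(f"{self.component_id}: ranks outside [1, x]")
        expected = self.x * (self.x + 1) / 2
        if not np.isclose(r.sum(), expected, rtol=0, atol=1e-8 * max(1.0, expected)):
            raise ValidationError(
                f"{self.component_id}: rank sum {r.sum()} != x(x+1)/2 = {expected}"
            )


@dataclass
class RscoreConfig:
    """Weights and policies for the integrated score.

    ``components`` is an ordered list of (component_id, weight c_i >= 0);
    ``None`` means "every supplied component, weight 1".  Under
    ``missing_policy='intersection'`` only proteins present in every
    weighted component are scored with n = number of weighted components;
    under ``'adjusted_n'`` n is the per-protein count of available
    components.  ``rank_scale='percentile'`` divides each rank by its
    component's x before weighting.
    """

    components: list[tuple[str, float]] | None = None
    missing_policy: str = "intersection"
    rank_scale: str = "absolute"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.missing_policy not in ("intersection", "adjusted_n"):
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")
        if self.rank_scale not in ("absolute", "percentile"):
            raise ValidationError(f"unknown rank_scale {self.rank_scale!r}")
        if self.components is not None:
            if any(w < 0 for _, w in self.components):
                raise ValidationError("component weights must be >= 0")
            if not any(w > 0 for _, w in self.components):
                raise ValidationError("at least one component weight must be > 0")

    def weights_for(self, component_ids: list[str]) -> dict[str, float]:
        """Resolve the effective weight of each supplied component."""
        if self.components is None:
            return {cid: 1.0 for cid in component_ids}
        return {cid: w for cid, w in self.components if cid in set(component_ids)}


@dataclass
class CandidateReport:
    """Final sorted Rscore table plus provenance.

    ``table`` rows are sorted by Rscore ascending (smallest = best) with
    final_rank 1..K and deterministic lexicographic tie-break on
    accession.  ``provenance`` echoes config, seed and dataset ids.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"symbol", "accession", "Rscore", "n_used", "final_rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"report missing columns {sorted(missing)}")
        if len(self.table):
            if self.table["Rscore"].isna().any():
                raise ValidationError("report contains NaN Rscore")
            scores = self.table["Rscore"].to_numpy(dtype=float)
            if (np.diff(scores) < -1e-12).any():
                raise ValidationError("report not sorted by Rscore ascending")
            ranks = self.table["final_rank"].to_numpy()
            if not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
                raise ValidationError("final_rank must be 1..K in order")

    def top(self, k: int) -> list[str]:
        """Symbols of the k best-ranked candidates."""
        return self.table["symbol"].head(k).tolist()
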
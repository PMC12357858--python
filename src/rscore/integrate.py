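"""Weighted rank aggregation of component scores.

Each component's metric values become a rank vector r_i over the
proteins detected in that component: rank 1 is best, rank x worst, with
ties receiving the average of the covered positions (so every vector
sums to x(x+1)/2).  The integrated score of protein p is

    Rscore(p) = sum_i r_i(p) * c_i / n,

where c_i is the component's constant weight and n the number of
integrated ranks; the smallest Rscore is the top candidate.  With all
weights equal this is Borda-style mean-rank consensus.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import CandidateReport, ComponentScore, RankVector, RscoreConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)


def rank_with_direction(score: ComponentScore) -> RankVector:
    """Rank a component's values; best value gets rank 1.

    ``higher_is_better`` metrics are ranked descending, ``lower_is_better``
    ascending; ties take the average of the covered positions.  Proteins
    with missing values are absent from the vector.
    """
    values = score.values.dropna()
    if values.empty:
        raise ValidationError(f"{score.component_id}: all values missing")
    v = values.to_numpy(dtype=float)
    if score.direction == "higher_is_better":
        v = -v
    ranks = rankdata(v, method="average")
    return RankVector(
        component_id=score.component_id,
        ranks=pd.Series(ranks, index=values.index),
        x=len(values),
    )


def intersect_candidates(protein_sets: list[set[str]]) -> list[str]:
    """Intersection of symbol sets, deterministically sorted."""
    if not protein_sets:
        raise ValidationError("need at least one protein set")
    common = set(protein_sets[0])
    for s in protein_sets[1:]:
        common &= set(s)
    return sorted(common)


def compute_rscore(
    rank_vectors: list[RankVector],
    config: RscoreConfig,
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted mean of component ranks per protein.

    Returns a DataFrame indexed by symbol with columns ``Rscore`` and
    ``n_used``.  Under missing_policy='intersection' only proteins ranked
    in every weighted component are scored and n is the component count;
    under 'adjusted_n' n is the per-protein count of available components.
    ``candidates`` optionally restricts the scored universe first.
    """
    weights = config.weights_for([rv.component_id for rv in rank_vectors])
    used = [rv for rv in rank_vectors if weights.get(rv.component_id, 0.0) > 0]
    if not used:
        raise ValidationError("no component with positive weight")

    rank_table = pd.DataFrame(
        {
            rv.component_id: (rv.ranks / rv.x if config.rank_scale == "percentile"
                              else rv.ranks)
            for rv in used
        }
    )
    if candidates is not None:
        rank_table = rank_table.reindex([c for c in candidates if c in rank_table.index])

    w = np.array([weights[rv.component_id] for rv in used], dtype=float)
    weighted = rank_table.to_numpy(dtype=float) * w

    if config.missing_policy == "intersection":
        complete = rank_table.notna().all(axis=1)
        rank_table = rank_table[complete]
        weighted = weighted[complete.to_numpy()]
        n_used = np.full(len(rank_table), len(used))
        rscore = weighted.sum(axis=1) / len(used)
    else:  # adjusted_n
        n_used = rank_table.notna().sum(axis=1).to_numpy()
        keep = n_used > 0
        rank_table, weighted, n_used = rank_table[keep], weighted[keep], n_used[keep]
        rscore = np.nansum(weighted, axis=1) / n_used

    if rank_table.empty:
        raise ValidationError("no protein scoreable under the missing-data policy")
    return pd.DataFrame(
        {"Rscore": rscore, "n_used": n_used.astype(np.int64)}, index=rank_table.index
    )


def final_ranking(
    rscores: pd.DataFrame,
    accessions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sort ascending by Rscore; ties break lexicographically by accession.

    Returns the report rows (symbol, accession, Rscore, n_used,
    final_rank); the accession falls back to the symbol when no mapping
    is supplied.
    """
    if rscores.empty:
        raise ValidationError("empty Rscore table")
    accessions = accessions or {}
    out = rscores.copy()
    out["symbol"] = out.index.astype(str)
    out["accession"] = [accessions.get(s, s) for s in out["symbol"]]
    out = out.sort_values(["Rscore", "accession"], kind="stable").reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out[["symbol", "accession", "Rscore", "n_used", "final_rank"]]


def build_report(
    component_scores: list[ComponentScore],
    config: RscoreConfig,
    candidates: list[str] | None = None,
    accessions: dict[str, str] | None = None,
    provenance: dict | None = None,
) -> CandidateReport:
    """Full integration: rank every component, score, sort, annotate.

    The report carries one rank column and one metric column per weighted
    component in addition to the core columns.
    """
    weights = config.weights_for([cs.component_id for cs in component_scores])
    used_scores = [cs for cs in component_scores if weights.get(cs.component_id, 0) > 0]
    rank_vectors = [rank_with_direction(cs) for cs in used_scores]
    rscores = compute_rscore(rank_vectors, config, candidates=candidates)
    table = final_ranking(rscores, accessions=accessions)

    for cs, rv in zip(used_scores, rank_vectors):
        table[f"rank_{cs.component_id}"] = rv.ranks.reindex(table["symbol"]).to_numpy()
        table[f"metric_{cs.component_id}"] = cs.values.reindex(table["symbol"]).to_numpy()

    provenance = dict(provenance or {})
    sizes = [rv.x for rv in rank_vectors]
    if sizes and max(sizes) > 2 * min(sizes) and config.rank_scale == "absolute":
        note = (f"component sizes differ by >2x ({min(sizes)}..{max(sizes)}); "
                "absolute ranks are not commensurable across datasets — "
                "consider rank_scale='percentile'")
        logger.info(note)
        provenance.setdefault("rank_scale_note", note)
    return CandidateReport(table=table, provenance=provenance)
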
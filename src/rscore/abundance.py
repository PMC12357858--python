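"""Length-normalized relative protein abundance.

Spectral (or PSM) counts scale with protein length: a longer protein
yields more tryptic peptides and hence more spectra at equal molar
amount.  The abundance component therefore divides each protein's total
count by the ratio of its length to the dataset's median protein length,

    abundance_p = counts_p / (length_p / median(lengths)),

so a protein of median length keeps its raw count and a protein twice
the median length is halved.  Higher normalized abundance ranks better.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import ComponentScore, QuantDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


def summarize_counts(
    dataset: QuantDataset, conditions_included: set[str]
) -> pd.Series:
    """Total counts per protein over the samples with included conditions.

    Present values are summed; a protein missing (NA) in *all* included
    samples is flagged undetected and excluded from the result.
    """
    samples = dataset.samples_for(conditions_included)
    if not samples:
        raise ValidationError(
            f"{dataset.dataset_id}: no samples with conditions {sorted(conditions_included)}"
        )
    sub = dataset.abundance[samples]
    detected = sub.notna().any(axis=1)
    if (~detected).any():
        logger.info(
            "%s: %d proteins undetected in all included samples, excluded",
            dataset.dataset_id, int((~detected).sum()),
        )
    return sub[detected].sum(axis=1, skipna=True)


def normalize_abundance(
    counts: pd.Series,
    lengths: pd.Series,
    dataset_id: str = "",
) -> ComponentScore:
    """Divide counts by the protein-length ratio to the dataset median.

    ``counts`` and ``lengths`` must cover the same proteins.  The median
    is taken over the proteins present in this dataset (midpoint of the
    two central values for even counts).
    """
    if len(counts) == 0:
        raise ValidationError(f"{dataset_id}: empty protein set")
    lengths = lengths.loc[counts.index]
    if (counts < 0).any():
        raise ValidationError(f"{dataset_id}: negative counts")
    if (lengths < 1).any():
        raise ValidationError(f"{dataset_id}: lengths must be >= 1")
    median_length = float(np.median(lengths.to_numpy(dtype=float)))
    values = counts.astype(float) / (lengths.astype(float) / median_length)
    return ComponentScore(
        component_id=f"abundance:{dataset_id}" if dataset_id else "abundance",
        dataset_id=dataset_id,
        metric_name="abundance",
        values=values,
    )


def abundance_component(
    dataset: QuantDataset, conditions_included: set[str] | None = None
) -> ComponentScore:
    """Convenience: summed counts -> length-normalized abundance score.

    By default every non-``normal`` sample contributes (tumor tissue,
    cell lines and CTCs are all "signal" conditions for abundance).
    """
    if conditions_included is None:
        conditions_included = {"tumor", "cell_line", "ctc"}
    counts = summarize_counts(dataset, conditions_included)
    lengths = dataset.proteins["length_aa"].loc[counts.index]
    return normalize_abundance(counts, lengths, dataset_id=dataset.dataset_id)
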
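"""Synthetic multi-dataset proteomic studies with planted driver proteins.

The generator emulates the statistical structure the ranking pipeline
consumes: spectral-count-like abundances whose expectation scales with
protein length (so the length normalization is exercised non-trivially),
tumor-vs-normal differential expression, per-dataset detection dropout,
and a survival cohort in which planted drivers carry an
expression-dependent hazard.  Counts follow a negative binomial with
quadratic overdispersion (var = mu + dispersion * mu^2).

A study consists of one tumor-tissue dataset (tumor + matched-normal
samples), two cell-line datasets and one CTC dataset, a gene set (the
candidate universe), and a survival cohort covering the gene-set
proteins.  Planted drivers carry all three signals: high abundance
(above a configurable percentile), a tumor fold change, and an adverse
hazard above their median expression.  Drivers are exempt from dropout
so they are scoreable in every dataset, mirroring a workflow that only
scores proteins detected across all datasets.

One global seed fans out to independent per-dataset generator streams,
so adding a dataset does not perturb the others; the same seed yields a
bit-identical study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import GeneSet, QuantDataset, SurvivalCohort
from .errors import ValidationError
from . import io as rio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticParams:
    """Study-generation parameters (defaults define the standard conditions).

    Lengths (amino acids) are log-normal(meanlog ln 400, sdlog 0.5)
    floored at 50; base abundances log-normal(meanlog ln 10, sdlog 1);
    counts are negative binomial with mean
    ``abundance * (length / median length) * sample depth`` and
    dispersion 0.2; sample depths log-normal(0, 0.25).  Detection dropout
    is logistic in log abundance with midpoint at the 20th abundance
    percentile.  The cohort has 200 patients, baseline hazard 0.02 per
    time unit, censoring uniform on (0, 60].
    """

    n_proteins: int = 500
    n_gene_set: int = 150
    n_drivers: int = 3
    length_meanlog: float = float(np.log(400.0))
    length_sdlog: float = 0.5
    length_floor: int = 50
    abundance_meanlog: float = float(np.log(10.0))
    abundance_sdlog: float = 1.0
    nb_dispersion: float = 0.2
    depth_sdlog: float = 0.25
    tumor_fold: float = 4.0
    dropout_midpoint_quantile: float = 0.20
    dropout_scale: float = 1.0
    driver_abundance_quantile: float | None = 0.75
    n_tumor: int = 6
    n_normal: int = 6
    n_cell_line: int = 3
    n_ctc: int = 3
    n_patients: int = 200
    hr_true: float = 2.5
    expression_sdlog: float = 0.5
    baseline_hazard: float = 0.02
    censor_horizon: float = 60.0

    def __post_init__(self) -> None:
        if not (self.n_drivers <= self.n_gene_set <= self.n_proteins):
            raise ValidationError("need n_drivers <= n_gene_set <= n_proteins")
        if self.n_drivers < 0 or self.tumor_fold <= 0 or self.hr_true <= 0:
            raise ValidationError("invalid parameters")
        if self.nb_dispersion <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("invalid parameters")


@dataclass
class SyntheticStudy:
    """A generated study: quant datasets, cohort, gene set, planted truth."""

    datasets: list[QuantDataset]
    cohort: SurvivalCohort
    gene_set: GeneSet
    truth: dict = field(default_factory=dict)


def nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mu, 1e-12))
    return rng.negative_binomial(size, p)


def _quant_dataset(
    rng: np.random.Generator,
    dataset_id: str,
    symbols: np.ndarray,
    accessions: np.ndarray,
    lengths: np.ndarray,
    abundance: np.ndarray,
    sample_conditions: list[tuple[str, str]],
    params: SyntheticParams,
    driver_mask: np.ndarray,
) -> QuantDataset:
    """Simulate one dataset's count matrix with dropout (drivers exempt)."""
    n_p = len(symbols)
    length_ratio = lengths / np.median(lengths)
    depths = rng.lognormal(0.0, params.depth_sdlog, size=len(sample_conditions))

    matrix = np.empty((n_p, len(sample_conditions)), dtype=float)
    for j, (_, condition) in enumerate(sample_conditions):
        a = abundance.copy()
        if condition == "tumor":
            a[driver_mask] *= params.tumor_fold
        mu = a * length_ratio * depths[j]
        matrix[:, j] = nb_counts(rng, mu, params.nb_dispersion)

    # protein-level detection dropout, logistic in log abundance
    log_a = np.log(abundance)
    midpoint = np.quantile(log_a, params.dropout_midpoint_quantile)
    p_drop = expit(-(log_a - midpoint) / params.dropout_scale)
    dropped = (rng.random(n_p) < p_drop) & ~driver_mask
    matrix[dropped, :] = np.nan

    proteins = pd.DataFrame(
        {"accession": accessions, "length_aa": lengths.astype(np.int64)},
        index=pd.Index(symbols, name="symbol"),
    )
    sample_ids = [sid for sid, _ in sample_conditions]
    return QuantDataset(
        dataset_id=dataset_id,
        proteins=proteins,
        abundance=pd.DataFrame(matrix, index=proteins.index, columns=sample_ids),
        conditions=pd.Series([c for _, c in sample_conditions], index=sample_ids),
    )


def generate_study(params: SyntheticParams | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full multi-dataset study with planted drivers.

    Drivers carry high abundance (unless ``driver_abundance_quantile`` is
    None), a tumor fold change of ``tumor_fold`` in the tissue dataset,
    and a hazard ratio ``hr_true`` above their median cohort expression.
    """
    if params is None:
        params = SyntheticParams()
    ss = np.random.SeedSequence(seed)
    s_prot, s_tissue, s_cl1, s_cl2, s_ctc, s_cohort = ss.spawn(6)
    rng = np.random.default_rng(s_prot)

    n = params.n_proteins
    symbols = np.array([f"GENE{i:04d}" for i in range(n)])
    accessions = np.array([f"SYNP{i:05d}" for i in range(n)])
    lengths = np.maximum(
        np.round(rng.lognormal(params.length_meanlog, params.length_sdlog, n)),
        params.length_floor,
    ).astype(np.int64)
    abundance = rng.lognormal(params.abundance_meanlog, params.abundance_sdlog, n)

    gene_set_idx = rng.choice(n, size=params.n_gene_set, replace=False)
    driver_idx = rng.choice(gene_set_idx, size=params.n_drivers, replace=False)
    driver_mask = np.zeros(n, dtype=bool)
    driver_mask[driver_idx] = True
    if params.driver_abundance_quantile is not None:
        # plant drivers above the chosen abundance percentile
        q = params.driver_abundance_quantile
        abundance[driver_idx] = np.quantile(
            abundance, rng.uniform(q, 1.0, size=params.n_drivers)
        )

    def samples(prefix: str, count: int, condition: str) -> list[tuple[str, str]]:
        return [(f"{prefix}{k + 1}", condition) for k in range(count)]

    tissue_samples = samples("T", params.n_tumor, "tumor") + samples(
        "N", params.n_normal, "normal"
    )
    datasets = [
        _quant_dataset(np.random.default_rng(s_tissue), "tumor_tissue", symbols,
                       accessions, lengths, abundance, tissue_samples, params,
                       driver_mask),
        _quant_dataset(np.random.default_rng(s_cl1), "cell_line_1", symbols,
                       accessions, lengths, abundance,
                       samples("CL1_", params.n_cell_line, "cell_line"), params,
                       driver_mask),
        _quant_dataset(np.random.default_rng(s_cl2), "cell_line_2", symbols,
                       accessions, lengths, abundance,
                       samples("CL2_", params.n_cell_line, "cell_line"), params,
                       driver_mask),
        _quant_dataset(np.random.default_rng(s_ctc), "ctc", symbols, accessions,
                       lengths, abundance,
                       samples("CTC", params.n_ctc, "ctc"), params, driver_mask),
    ]

    gene_set_symbols = sorted(symbols[gene_set_idx])
    gene_set = GeneSet(name="SYNTHETIC_ADHESION", members=frozenset(gene_set_symbols))
    driver_symbols = sorted(symbols[driver_idx])

    cohort = _survival_cohort(
        np.random.default_rng(s_cohort), gene_set_symbols, driver_symbols,
        dict(zip(symbols, abundance)), params,
    )

    truth = {
        "drivers": driver_symbols,
        "tumor_fold": params.tumor_fold,
        "hr_true": params.hr_true,
        "driver_abundance_quantile": params.driver_abundance_quantile,
        "seed": seed,
        "params": asdict(params),
    }
    return SyntheticStudy(datasets=datasets, cohort=cohort, gene_set=gene_set,
                          truth=truth)


def _survival_cohort(
    rng: np.random.Generator,
    proteins: list[str],
    drivers: list[str],
    base_abundance: dict[str, float],
    params: SyntheticParams,
) -> SurvivalCohort:
    """Cohort whose hazard multiplies by hr_true above each driver's median."""
    n = params.n_patients
    expr = {
        p: rng.lognormal(np.log(base_abundance[p]), params.expression_sdlog, n)
        for p in proteins
    }
    hazard = np.full(n, params.baseline_hazard)
    for d in drivers:
        high = expr[d] > np.median(expr[d])
        hazard = hazard * np.where(high, params.hr_true, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.maximum(rng.uniform(0.0, params.censor_horizon, n), 1e-9)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(np.int64)

    data = pd.DataFrame(expr, index=pd.Index(
        [f"PT{i:04d}" for i in range(n)], name="patient_id"))
    data.insert(0, "event", event)
    data.insert(0, "time", time)
    return SurvivalCohort(cohort_id="synthetic_cohort", endpoint="OS", data=data)


def simulate_survival_cohort(
    n: int,
    hr_true: float,
    split_quantile: float = 0.5,
    baseline_hazard: float = 0.02,
    censor_horizon: float = 60.0,
    seed: int = 0,
) -> SurvivalCohort:
    """Single-marker cohort: hazard = baseline below the split, x hr_true above.

    Event times are exponential; censoring is uniform on (0, censor_horizon].
    """
    if n < 10:
        raise ValidationError("need n >= 10 patients")
    if hr_true <= 0 or baseline_hazard <= 0 or censor_horizon < 0:
        raise ValidationError("invalid parameters")
    if not 0 < split_quantile < 1:
        raise ValidationError("split_quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    expr = rng.lognormal(0.0, 1.0, n)
    high = expr > np.quantile(expr, split_quantile)
    hazard = np.where(high, baseline_hazard * hr_true, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.maximum(rng.uniform(0.0, censor_horizon, n), 1e-12)
    time = np.maximum(np.minimum(event_time, censor_time), 1e-12)
    event = (event_time <= censor_time).astype(np.int64)
    if event.sum() == 0:
        logger.warning("simulated cohort has zero events")
    data = pd.DataFrame(
        {"time": time, "event": event, "MARKER": expr},
        index=pd.Index([f"PT{i:04d}" for i in range(n)], name="patient_id"),
    )
    return SurvivalCohort(cohort_id=f"sim_n{n}", endpoint="OS", data=data)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write a study directory: quant TSVs + sample sheets, GMT, survival, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in study.datasets:
        rio.write_quant_table(ds, out / f"{ds.dataset_id}.tsv",
                              out / f"{ds.dataset_id}.samples.tsv")
    rio.write_gene_set(study.gene_set, out / "gene_set.gmt")
    rio.write_survival_table(study.cohort, out / "survival.tsv")
    truth = pd.DataFrame({"driver": study.truth.get("drivers", [])})
    truth["tumor_fold"] = study.truth.get("tumor_fold")
    truth["hr_true"] = study.truth.get("hr_true")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
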
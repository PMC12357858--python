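"""End-to-end orchestration: load, filter, score, integrate, report.

The stage order mirrors the analysis workflow: restrict every
quantification dataset to the candidate gene set; compute one
length-normalized abundance component per dataset; compute the
tumor-vs-normal specificity components on datasets with both tumor and
normal samples; compute the survival components per cohort; intersect
the proteins detected in every dataset; aggregate the component ranks
into the integrated score; and write the sorted candidate report with
full provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import abundance_component
from .datamodel import CandidateReport, ComponentScore, QuantDataset, RscoreConfig
from .errors import ValidationError
from .integrate import build_report, intersect_candidates
from .io import (
    filter_to_gene_set,
    read_gene_set,
    read_quant_table,
    read_survival_table,
    write_candidate_report,
)
from .simulate import SyntheticStudy
from .specificity import dataset_specificity
from .survival import ScanConfig, cohort_association

logger = logging.getLogger(__name__)

_REPORT_COLUMNS = ["symbol", "accession", "Rscore", "n_used", "final_rank"]


@dataclass
class PipelineConfig:
    """Paths and settings for a full ranking run (YAML-serializable)."""

    datasets: list[dict] = field(default_factory=list)
    gene_set: str = ""
    cohorts: list[dict] = field(default_factory=list)
    rscore: RscoreConfig = field(default_factory=RscoreConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    pseudocount: float | None = None
    out: str | None = None
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        rs = raw.get("rscore") or {}
        components = rs.get("components")
        if components is not None:
            components = [(str(c), float(w)) for c, w in components]
        rscore = RscoreConfig(
            components=components,
            missing_policy=rs.get("missing_policy", "intersection"),
            rank_scale=rs.get("rank_scale", "absolute"),
            seed=raw.get("seed"),
        )
        sc = raw.get("scan") or {}
        scan = ScanConfig(
            q_lo=float(sc.get("q_lo", 0.10)),
            q_hi=float(sc.get("q_hi", 0.90)),
            min_group=sc.get("min_group"),
        )
        return cls(
            datasets=raw.get("datasets") or [],
            gene_set=raw.get("gene_set", ""),
            cohorts=raw.get("cohorts") or [],
            rscore=rscore,
            scan=scan,
            pseudocount=raw.get("pseudocount"),
            out=raw.get("out"),
            seed=raw.get("seed"),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "datasets": self.datasets,
            "gene_set": self.gene_set,
            "cohorts": self.cohorts,
            "rscore": {
                "components": (None if self.rscore.components is None
                               else [[c, w] for c, w in self.rscore.components]),
                "missing_policy": self.rscore.missing_policy,
                "rank_scale": self.rscore.rank_scale,
            },
            "scan": {"q_lo": self.scan.q_lo, "q_hi": self.scan.q_hi,
                     "min_group": self.scan.min_group},
            "pseudocount": self.pseudocount,
            "out": self.out,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


def _empty_report(provenance: dict) -> CandidateReport:
    table = pd.DataFrame({c: pd.Series(dtype=float) for c in _REPORT_COLUMNS})
    return CandidateReport(table=table, provenance=provenance)


def rank_study(
    study: SyntheticStudy,
    rscore_config: RscoreConfig | None = None,
    scan: ScanConfig | None = None,
    pseudocount: float | None = None,
    provenance: dict | None = None,
) -> CandidateReport:
    """Run the scoring stages on in-memory study objects.

    Returns the sorted candidate report; an empty cross-dataset
    intersection yields an empty report (logged), not an error.
    """
    rscore_config = rscore_config or RscoreConfig()
    scan = scan or ScanConfig()
    provenance = dict(provenance or {})
    provenance.setdefault("tool_version", __version__)
    provenance.setdefault("dataset_ids",
                          ",".join(ds.dataset_id for ds in study.datasets))
    provenance.setdefault("missing_policy", rscore_config.missing_policy)
    provenance.setdefault("rank_scale", rscore_config.rank_scale)

    filtered = [filter_to_gene_set(ds, study.gene_set) for ds in study.datasets]
    components: list[ComponentScore] = []
    detected_sets: list[set[str]] = []
    accessions: dict[str, str] = {}

    for ds in filtered:
        if ds.abundance.empty:
            logger.warning("%s: empty after gene-set filter", ds.dataset_id)
            detected_sets.append(set())
            continue
        comp = abundance_component(ds)
        components.append(comp)
        detected_sets.append(set(comp.values.index))
        for symbol, acc in ds.proteins["accession"].items():
            accessions.setdefault(symbol, acc)

    candidates = intersect_candidates(detected_sets)
    logger.info("%d candidates in the cross-dataset intersection", len(candidates))
    if not candidates:
        logger.warning("empty candidate intersection: writing empty report")
        return _empty_report(provenance)
    candidate_set = set(candidates)

    for ds in filtered:
        tumor = ds.samples_for({"tumor"})
        normal = ds.samples_for({"normal"})
        if len(tumor) >= 2 and len(normal) >= 2:
            scores, _ = dataset_specificity(ds, pseudocount=pseudocount)
            components.extend(scores)

    # only the intersected candidates proceed to the clinical-association
    # stage, mirroring a workflow where the overlapped top candidates are
    # the ones queried against survival cohorts
    cohorts = study.cohort if isinstance(study.cohort, list) else [study.cohort]
    for cohort in cohorts:
        proteins = [p for p in cohort.proteins if p in candidate_set]
        scores, _ = cohort_association(cohort, proteins=proteins, scan=scan)
        components.extend(scores)
    try:
        return build_report(components, rscore_config, candidates=candidates,
                            accessions=accessions, provenance=provenance)
    except ValidationError as exc:
        logger.warning("no scoreable candidates (%s): writing empty report", exc)
        return _empty_report(provenance)


def run_pipeline(config: PipelineConfig) -> CandidateReport:
    """Load all inputs named by the config, rank, and write the report."""
    if not config.datasets:
        raise ValidationError("pipeline config lists no datasets")
    if not config.gene_set:
        raise ValidationError("pipeline config lists no gene set")

    datasets: list[QuantDataset] = []
    for spec in config.datasets:
        datasets.append(
            read_quant_table(spec["quant"], spec["samples"],
                             dataset_id=spec.get("id"))
        )
    gene_set = read_gene_set(config.gene_set)
    cohorts = [
        read_survival_table(spec["path"], cohort_id=spec.get("id"),
                            endpoint=spec.get("endpoint", "OS"))
        for spec in config.cohorts
    ]
    study = SyntheticStudy(datasets=datasets, cohort=cohorts, gene_set=gene_set)

    provenance = {
        "seed": config.seed,
        "gene_set": gene_set.name,
        "n_gene_set": len(gene_set),
        "scan": f"q_lo={config.scan.q_lo},q_hi={config.scan.q_hi},"
                f"min_group={config.scan.min_group}",
    }
    report = rank_study(study, rscore_config=config.rscore, scan=config.scan,
                        pseudocount=config.pseudocount, provenance=provenance)
    if config.out:
        write_candidate_report(report, config.out)
        logger.info("report written to %s", config.out)
    return report
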
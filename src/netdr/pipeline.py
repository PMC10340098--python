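"""End-to-end orchestration: FIN + disease cohort + drug library → ranked
candidate table.

For each drug the pipeline builds the drug-affected protein network (DAPN)
from its |z| > 1 DEGs, scores the genes of the DAPN and of the disease gene
network (DGN) with each requested metric, applies the z-score adjustment,
ranks, and computes the bidirectional combined AUC.  Drugs are then sorted
per metric by combined AUC and flagged as repositioning candidates above the
significance cutoff (0.6 by default).

The DGN and its drug-independent base scores (Adamic-Adar S_x, PageRank,
and the disease-side neighborhood scores) are computed once and reused for
every drug; only the z-adjustment, which depends on the drug's z-scores,
is re-applied per drug.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from netdr.network import WeightedNetwork, GeneModule, build_module, NetworkError
from netdr.signatures import (
    DrugSignature,
    DiseaseSignature,
    select_drug_degs,
    select_disease_degs,
    SignatureError,
)
from netdr.metrics import (
    METRICS,
    ScoreTable,
    adamic_adar_scores,
    pagerank_scores,
    neighborhood_scores,
    adjust_multiplicative,
    adjust_exponential,
)
from netdr.similarity import (
    DrugResult,
    UndefinedAUCError,
    rank_genes,
    roc_auc,
    confusion_metrics,
    combined_auc,
)

logger = logging.getLogger("netdr")

_NAN = float("nan")

RESULT_COLUMNS = [
    "drug",
    "metric",
    "auc_dapn",
    "auc_dgn",
    "combined_auc",
    "f1",
    "precision",
    "recall",
    "n_ranked",
    "n_reference",
]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, defaulting to the study values."""

    weight_floor: float = 0.1
    drug_z_threshold: float = 1.0
    fdr_threshold: float = 0.01
    fc_threshold: float = 2.0
    damping: float = 0.75
    alpha: float = 0.7
    epsilon: float = 0.1
    n_thresholds: int = 100
    auc_cutoff: float = 0.6
    metrics: tuple[str, ...] = METRICS
    rng_seed: int = 0

    def __post_init__(self):
        checks = [
            (0.0 <= self.weight_floor <= 1.0, "weight_floor in [0, 1]"),
            (self.drug_z_threshold >= 0.0, "drug_z_threshold >= 0"),
            (0.0 < self.fdr_threshold <= 1.0, "fdr_threshold in (0, 1]"),
            (self.fc_threshold >= 1.0, "fc_threshold >= 1"),
            (0.0 < self.damping < 1.0, "damping in (0, 1)"),
            (0.0 <= self.alpha <= 1.0, "alpha in [0, 1]"),
            (0.0 <= self.epsilon < 1.0, "epsilon in [0, 1)"),
            (self.n_thresholds >= 1, "n_thresholds >= 1"),
            (0.0 <= self.auc_cutoff <= 1.0, "auc_cutoff in [0, 1]"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"RunConfig: {what} violated")
        self.metrics = tuple(self.metrics)
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"RunConfig: unknown metrics {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["metrics"] = list(self.metrics)
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class DiseaseContext:
    """The DGN and its drug-independent scores, shared across the drug library."""

    dgn: GeneModule
    aa_base: dict[str, float]
    pr_base: dict[str, float]
    disease: DiseaseSignature


def _residual_z(module_other: GeneModule, z_self, z_other):
    """Residual perturbation magnitude fed to neighborhood scoring.

    For a gene in both modules this is |z_self + z_other| — the same
    quantity the Adamic-Adar/PageRank damping factors act on, ≈ 0 when the
    drug reverses the disease signal; for a module-private gene it is
    |z_self|.  Ranking these ascending puts the most-neutralized genes
    first, which is what the ascending AUC convention for neighborhood
    scoring rewards.
    """
    members = module_other.members

    def zf(gene: str) -> float:
        if gene in members:
            return abs(z_self(gene) + z_other(gene))
        return abs(z_self(gene))

    return zf


def build_disease_context(
    fin: WeightedNetwork, disease: DiseaseSignature, cfg: RunConfig
) -> DiseaseContext:
    """Build the DGN from the disease DEGs and precompute its base scores."""
    degs = select_disease_degs(disease, cfg.fdr_threshold, cfg.fc_threshold)
    dgn = build_module(fin, degs, kind="DGN")
    logger.info(
        "DGN: %d DEGs -> %d seeds mapped, %d members, %d edges",
        len(degs), len(dgn.seeds), dgn.n_members, dgn.subnetwork.n_edges,
    )
    return DiseaseContext(
        dgn=dgn,
        aa_base=adamic_adar_scores(dgn),
        pr_base=pagerank_scores(dgn, damping=cfg.damping),
        disease=disease,
    )


def _directional_auc(table: ScoreTable, reference: frozenset[str], cfg: RunConfig):
    ranked = rank_genes(table)
    curve = roc_auc(ranked, reference, n_thresholds=cfg.n_thresholds)
    return ranked, curve


def evaluate_drug(
    fin: WeightedNetwork,
    disease: DiseaseSignature,
    drug: DrugSignature,
    cfg: RunConfig,
    context: DiseaseContext | None = None,
) -> list[DrugResult]:
    """Score one drug against the disease with every requested metric.

    Returns one :class:`DrugResult` per metric.  A degenerate geometry
    (reference empty on, or covering, a ranked list) yields an NA row
    instead of raising, so a batch run can proceed.
    """
    if context is None:
        context = build_disease_context(fin, disease, cfg)
    dgn = context.dgn
    results: list[DrugResult] = []
    if not cfg.metrics:
        return results

    degs = select_drug_degs(drug, cfg.drug_z_threshold)
    dapn = build_module(fin, degs, kind="DAPN")
    logger.info(
        "drug %s: |DEG|=%d, DAPN members=%d, reference (DGN∩DAPN)=%d",
        drug.drug_id, len(degs), dapn.n_members, len(dapn.members & dgn.members),
    )

    # drug-side base scores, shared between the 1/2 variants of each family
    aa_dapn = pr_dapn = None
    if "AA1" in cfg.metrics or "AA2" in cfg.metrics:
        aa_dapn = adamic_adar_scores(dapn)
    if "PR1" in cfg.metrics or "PR2" in cfg.metrics:
        pr_dapn = pagerank_scores(dapn, damping=cfg.damping)

    for metric in cfg.metrics:
        if metric == "NS":
            dapn_table = ScoreTable(
                "NS",
                neighborhood_scores(
                    dapn, _residual_z(dgn, drug.z, disease.z), cfg.alpha, cfg.epsilon
                ),
            )
            dgn_table = ScoreTable(
                "NS",
                neighborhood_scores(
                    dgn, _residual_z(dapn, disease.z, drug.z), cfg.alpha, cfg.epsilon
                ),
            )
        else:
            adjust = adjust_multiplicative if metric in ("AA1", "PR1") else adjust_exponential
            base_dapn = aa_dapn if metric.startswith("AA") else pr_dapn
            base_dgn = context.aa_base if metric.startswith("AA") else context.pr_base
            dapn_table = ScoreTable(metric, adjust(base_dapn, dapn, dgn, drug, disease))
            dgn_table = ScoreTable(metric, adjust(base_dgn, dgn, dapn, disease, drug))
        try:
            ranked_dapn, curve_dapn = _directional_auc(dapn_table, dgn.members, cfg)
            _, curve_dgn = _directional_auc(dgn_table, dapn.members, cfg)
            ref_dapn_side = set(dgn.members) & set(ranked_dapn)
            precision, recall, f1 = confusion_metrics(ranked_dapn, dgn.members)
            results.append(
                DrugResult(
                    drug_id=drug.drug_id,
                    metric=metric,
                    auc_dapn=curve_dapn.auc,
                    auc_dgn=curve_dgn.auc,
                    combined_auc=combined_auc(curve_dapn.auc, curve_dgn.auc),
                    f1=f1,
                    precision=precision,
                    recall=recall,
                    n_ranked=len(ranked_dapn),
                    n_reference=len(ref_dapn_side),
                )
            )
        except UndefinedAUCError as exc:
            logger.warning("drug %s metric %s: AUC undefined (%s)", drug.drug_id, metric, exc)
            results.append(
                DrugResult(
                    drug_id=drug.drug_id,
                    metric=metric,
                    auc_dapn=_NAN,
                    auc_dgn=_NAN,
                    combined_auc=_NAN,
                    n_ranked=dapn.n_members,
                    n_reference=len(dapn.members & dgn.members),
                )
            )
    return results


def results_table(results: list[DrugResult]) -> pd.DataFrame:
    rows = [
        {
            "drug": r.drug_id,
            "metric": r.metric,
            "auc_dapn": r.auc_dapn,
            "auc_dgn": r.auc_dgn,
            "combined_auc": r.combined_auc,
            "f1": r.f1,
            "precision": r.precision,
            "recall": r.recall,
            "n_ranked": r.n_ranked,
            "n_reference": r.n_reference,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def rank_drugs(results: list[DrugResult], cfg: RunConfig) -> pd.DataFrame:
    """Per metric, sort drugs by combined AUC (descending, drug-id tie-break)
    and flag rows at or above the significance cutoff as candidates.

    NA rows sort last and are never candidates.
    """
    df = results_table(results)
    if df.empty:
        logger.warning("rank_drugs: no results to rank")
        df["rank"] = pd.Series(dtype=int)
        df["is_candidate"] = pd.Series(dtype=bool)
        return df
    df = df.sort_values(
        ["metric", "combined_auc", "drug"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("metric").cumcount() + 1
    df["is_candidate"] = df["combined_auc"] >= cfg.auc_cutoff
    if not df["is_candidate"].any():
        logger.warning("rank_drugs: no candidate above combined AUC %.2f", cfg.auc_cutoff)
    return df


def run_study(
    fin: WeightedNetwork,
    disease: DiseaseSignature,
    drugs: list[DrugSignature],
    cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Evaluate a drug library and (optionally) write the output tables.

    A drug whose evaluation fails outright (e.g. empty DEG set, no seed on
    the network) is skipped and logged rather than aborting the batch.
    Writes ``results.tsv``, ``candidates.tsv`` and ``config.resolved.yaml``
    when ``out_dir`` is given; identical inputs produce byte-identical files.
    """
    context = build_disease_context(fin, disease, cfg)
    results: list[DrugResult] = []
    for drug in drugs:
        try:
            results.extend(evaluate_drug(fin, disease, drug, cfg, context))
        except (SignatureError, NetworkError) as exc:
            logger.warning("skipping drug %s: %s", drug.drug_id, exc)
    ranked = rank_drugs(results, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranked.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6f")
        ranked[ranked["is_candidate"]].to_csv(
            out / "candidates.tsv", sep="\t", index=False, float_format="%.6f"
        )
        cfg.to_yaml(out / "config.resolved.yaml")
    return ranked
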
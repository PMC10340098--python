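"""Drug and disease expression signatures and their DEG filters.

A drug signature is a gene → z-score table from a perturbation experiment
(LINCS-L1000 style; one table per drug/dose/cell line).  A disease signature
is a differential-expression table with per-gene log2 fold-change, FDR, and a
signed z-score.  Differentially expressed genes (DEGs) are selected with the
thresholds used throughout the pipeline: drug |z| > 1 (strict), disease
FDR < 0.01 and absolute linear fold-change ≥ 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd


class SignatureError(ValueError):
    """Invalid signature content or an empty DEG set."""


class EmptyDEGError(SignatureError):
    """The DEG filter returned no gene; the signature is unusable."""


class DiseaseRecord(NamedTuple):
    log2fc: float
    fdr: float
    z: float


@dataclass
class DrugSignature:
    """Per-drug transcriptome signature: gene → differential-expression z."""

    drug_id: str
    zscores: dict[str, float]
    cell_line: str = ""
    dose: str = ""
    deg_threshold: float = 1.0

    def __post_init__(self):
        for g, z in self.zscores.items():
            if not math.isfinite(z):
                raise SignatureError(f"drug {self.drug_id}: non-finite z for gene {g}")

    def z(self, gene: str) -> float:
        """Stored z-score, or 0.0 for an unmeasured gene (neutral element:
        the adjustment factors 0.5^|z| and e^|z| reduce to 1)."""
        return self.zscores.get(gene, 0.0)

    @property
    def genes(self) -> set[str]:
        return set(self.zscores)


@dataclass
class DiseaseSignature:
    """Disease cohort differential-expression table.

    The signed disease z-score is an input column (e.g. a DE z-statistic
    from the upstream cohort analysis); it is consumed as given, not derived.
    """

    cohort_id: str
    records: dict[str, DiseaseRecord]
    fdr_threshold: float = 0.01
    fc_threshold: float = 2.0

    def __post_init__(self):
        fixed = {}
        for g, rec in self.records.items():
            rec = DiseaseRecord(*map(float, rec))
            if not all(math.isfinite(v) for v in rec):
                raise SignatureError(f"cohort {self.cohort_id}: non-finite value for gene {g}")
            if not 0.0 <= rec.fdr <= 1.0:
                raise SignatureError(
                    f"cohort {self.cohort_id}: FDR {rec.fdr} outside [0, 1] for gene {g}"
                )
            fixed[g] = rec
        self.records = fixed

    def z(self, gene: str) -> float:
        """Stored disease z-score, or 0.0 for an unmeasured gene."""
        rec = self.records.get(gene)
        return rec.z if rec is not None else 0.0

    @property
    def genes(self) -> set[str]:
        return set(self.records)


def select_drug_degs(sig: DrugSignature, threshold: float | None = None) -> set[str]:
    """Genes with |z| strictly above the threshold (default: the signature's).

    Raises :class:`EmptyDEGError` when no gene passes, flagging the drug as
    unusable.
    """
    thr = sig.deg_threshold if threshold is None else threshold
    degs = {g for g, z in sig.zscores.items() if abs(z) > thr}
    if not degs:
        raise EmptyDEGError(f"drug {sig.drug_id}: no gene with |z| > {thr}")
    return degs


def select_disease_degs(
    sig: DiseaseSignature,
    fdr_threshold: float | None = None,
    fc_threshold: float | None = None,
) -> set[str]:
    """Genes with FDR < threshold and absolute linear fold-change ≥ threshold.

    The fold-change column is log2; the cutoff is applied on the linear
    scale as ``2^|log2FC| ≥ fc_threshold`` (non-strict, so a gene printed at
    exactly the threshold qualifies).  FDR is strict.
    """
    fdr_thr = sig.fdr_threshold if fdr_threshold is None else fdr_threshold
    fc_thr = sig.fc_threshold if fc_threshold is None else fc_threshold
    degs = {
        g
        for g, rec in sig.records.items()
        if rec.fdr < fdr_thr and 2.0 ** abs(rec.log2fc) >= fc_thr
    }
    if not degs:
        raise EmptyDEGError(
            f"cohort {sig.cohort_id}: no gene with FDR < {fdr_thr} and |FC| >= {fc_thr}"
        )
    return degs


def z_lookup(sig: DrugSignature | DiseaseSignature, gene: str) -> float:
    """z-score of ``gene`` in either signature kind; 0.0 when unmeasured."""
    return sig.z(gene)


# ---------------------------------------------------------------------------
# I/O — plain TSV tables
# ---------------------------------------------------------------------------

def read_drug_signature(
    path: str | Path,
    drug_id: str | None = None,
    cell_line: str = "",
    dose: str = "",
    deg_threshold: float = 1.0,
) -> DrugSignature:
    """Read a ``gene\tzscore`` TSV (header optional) as a DrugSignature."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "zscore"], dtype={0: str})
    if len(df) and not _is_number(df.iloc[0, 1]):
        df = df.iloc[1:]
    z = pd.to_numeric(df["zscore"], errors="raise").astype(float)
    return DrugSignature(
        drug_id=drug_id or path.stem,
        zscores=dict(zip(df["gene"].astype(str), z)),
        cell_line=cell_line,
        dose=dose,
        deg_threshold=deg_threshold,
    )


def read_disease_table(
    path: str | Path,
    cohort_id: str | None = None,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
) -> DiseaseSignature:
    """Read a ``gene\tlog2fc\tfdr\tz`` TSV (header optional)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "log2fc", "fdr", "z"], dtype={0: str}
    )
    if len(df) and not _is_number(df.iloc[0, 1]):
        df = df.iloc[1:]
    records = {
        str(row.gene): DiseaseRecord(float(row.log2fc), float(row.fdr), float(row.z))
        for row in df.itertuples()
    }
    return DiseaseSignature(
        cohort_id=cohort_id or path.stem,
        records=records,
        fdr_threshold=fdr_threshold,
        fc_threshold=fc_threshold,
    )


def read_drug_manifest(path: str | Path, deg_threshold: float = 1.0) -> list[DrugSignature]:
    """Read a manifest TSV ``drug_id\tcell_line\tdose\tpath`` and load each
    signature file (paths resolved relative to the manifest)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "cell_line", "dose", "path"}
    if not required <= set(df.columns):
        raise SignatureError(
            f"manifest {path.name} missing columns: {sorted(required - set(df.columns))}"
        )
    sigs = []
    for row in df.itertuples():
        sig_path = Path(row.path)
        if not sig_path.is_absolute():
            sig_path = path.parent / sig_path
        sigs.append(
            read_drug_signature(
                sig_path,
                drug_id=row.drug_id,
                cell_line=row.cell_line or "",
                dose=row.dose or "",
                deg_threshold=deg_threshold,
            )
        )
    return sigs


def write_drug_signature(sig: DrugSignature, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tzscore\n")
        for g in sorted(sig.zscores):
            fh.write(f"{g}\t{sig.zscores[g]:.10g}\n")


def write_disease_table(sig: DiseaseSignature, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tlog2fc\tfdr\tz\n")
        for g in sorted(sig.records):
            rec = sig.records[g]
            fh.write(f"{g}\t{rec.log2fc:.10g}\t{rec.fdr:.10g}\t{rec.z:.10g}\n")


def _is_number(tok) -> bool:
    try:
        float(tok)
        return True
    except (TypeError, ValueError):
        return False
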
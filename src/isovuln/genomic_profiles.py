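"""Per-study genomic profiles: discrete copy number and expression.

Copy-number input is a gene x sample matrix of discrete categories as
produced by GISTIC or RAE and exported by cBioPortal-style services:
-2 homozygous deletion, -1 heterozygous deletion, 0 diploid, 1 gain,
2 amplification.  Only the -2 category triggers a vulnerability call;
heterozygous loss is never sufficient.

Expression input, when a study has it, is either a gene x sample matrix
of Z-scores standardized against the study's diploid reference
(``zscore`` mode; values strictly below -2 count as underexpressed) or of
median-normalized log2 probe levels (``ccle_log2`` mode; values strictly
below 5 count as underexpressed, 5 being the upper limit of the lower
quartile of the pooled distribution for that panel).  Both cutoffs are
strict: a value exactly at the boundary is NOT underexpressed.  Studies
without expression return ``None`` ("unknown"), which never counts as
underexpressed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geneset_ingest import normalize_symbol

log = logging.getLogger(__name__)

CNA_CODES = (-2, -1, 0, 1, 2)
HOMDEL = -2

SAMPLE_CLASSES = ("tumor", "cell_line")
EXPRESSION_MODES = ("zscore", "ccle_log2", "none")

_NA_TOKENS = {"", "na", "nan", "null", "none"}


@dataclass(frozen=True)
class Thresholds:
    """All fixed cutoffs of the pipeline, overridable via config.

    ``zscore_cutoff`` / ``ccle_log2_cutoff`` are strict upper bounds for
    underexpression; ``homdel_code`` is the discrete category that counts
    as homozygous deletion; ``max_set_size`` bounds gene-set size;
    ``max_drug_targets`` bounds the target count of a selective drug.
    """

    zscore_cutoff: float = -2.0
    ccle_log2_cutoff: float = 5.0
    homdel_code: int = HOMDEL
    max_set_size: int = 5
    max_drug_targets: int = 5


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class StudyConfig:
    """Identity and file layout of one cancer study.

    ``tissue=None`` means the study has no tissue annotation, which
    disables tissue filtering for its samples.  ``expression_mode='none'``
    means no expression matrix exists and criterion (i) of the score can
    never be met for this study.
    """

    study_id: str
    cna_path: Optional[str] = None
    expr_path: Optional[str] = None
    tissue: Optional[str] = None
    sample_class: str = "tumor"
    expression_mode: str = "none"

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValueError(
                f"study {self.study_id!r}: sample_class must be one of "
                f"{SAMPLE_CLASSES}, got {self.sample_class!r}"
            )
        if self.expression_mode not in EXPRESSION_MODES:
            raise ValueError(
                f"study {self.study_id!r}: expression_mode must be one of "
                f"{EXPRESSION_MODES}, got {self.expression_mode!r}"
            )
        if self.expression_mode == "none" and self.expr_path:
            raise ValueError(
                f"study {self.study_id!r}: expression_mode='none' forbids an "
                "expression matrix path"
            )


@dataclass
class ProfileBundle:
    """Loaded matrices for one study.

    ``cna`` is a float DataFrame (genes x samples) holding discrete codes
    or NaN; ``expr`` is an optional float DataFrame whose samples are a
    subset of the CNA samples.
    """

    study: StudyConfig
    cna: pd.DataFrame
    expr: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.cna.columns.duplicated().any():
            dup = sorted(self.cna.columns[self.cna.columns.duplicated()])
            raise ValueError(f"study {self.study.study_id!r}: duplicate sample ids {dup}")
        vals = self.cna.to_numpy()
        finite = vals[np.isfinite(vals)]
        bad = finite[~np.isin(finite, CNA_CODES)]
        if bad.size:
            raise ValueError(
                f"study {self.study.study_id!r}: CNA values outside the "
                f"category codes {CNA_CODES}: {sorted(set(bad.tolist()))[:5]}"
            )
        if self.expr is not None:
            extra = set(self.expr.columns) - set(self.cna.columns)
            if extra:
                raise ValueError(
                    f"study {self.study.study_id!r}: expression samples not in "
                    f"CNA matrix: {sorted(extra)[:5]}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.cna.columns)


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV matrix (first column = gene symbols).

    Gene symbols are normalized; duplicate gene rows keep the first
    occurrence with a warning; NA-like cells become NaN.  A cell that is
    neither numeric nor NA raises an error naming the gene and sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: matrix needs a gene column plus >=1 sample column")
    gene_col = df.columns[0]
    genes = df[gene_col].map(normalize_symbol)
    body = df.drop(columns=[gene_col])
    body.index = genes

    def convert(cell: str, gene: str, sample: str) -> float:
        s = cell.strip()
        if s.lower() in _NA_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric cell {cell!r} at gene {gene!r}, sample {sample!r}"
            ) from None

    out = pd.DataFrame(
        {
            sample: [convert(v, g, sample) for g, v in zip(body.index, body[sample])]
            for sample in body.columns
        },
        index=body.index,
    )
    dup = out.index.duplicated()
    if dup.any():
        log.warning(
            "%s: %d duplicate gene row(s) (%s ...); first occurrence kept",
            path, int(dup.sum()), out.index[dup][0],
        )
        out = out[~dup]
    return out


def load_bundle(study: StudyConfig) -> ProfileBundle:
    """Load the matrices referenced by a study config."""
    if study.cna_path is None:
        raise ValueError(f"study {study.study_id!r}: no CNA matrix path")
    cna = read_profile_matrix(study.cna_path)
    expr = None
    if study.expression_mode != "none":
        if study.expr_path is None:
            raise ValueError(
                f"study {study.study_id!r}: expression_mode="
                f"{study.expression_mode!r} requires an expression matrix path"
            )
        expr = read_profile_matrix(study.expr_path)
    return ProfileBundle(study=study, cna=cna, expr=expr)


def is_homdel(
    bundle: ProfileBundle, gene: str, sample: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """True iff the discrete CNA code for (gene, sample) equals the
    homozygous-deletion code.  Genes or samples absent from the matrix,
    and NA cells, yield False (no evidence is never a deletion)."""
    gene = normalize_symbol(gene)
    if gene not in bundle.cna.index or sample not in bundle.cna.columns:
        log.debug("homdel: %s/%s absent from CNA matrix of %s",
                  gene, sample, bundle.study.study_id)
        return False
    value = bundle.cna.at[gene, sample]
    return bool(np.isfinite(value) and int(value) == thresholds.homdel_code)


def is_underexpressed(
    bundle: ProfileBundle, gene: str, sample: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Optional[bool]:
    """Underexpression call for (gene, sample): True/False, or None when
    it cannot be decided (no expression matrix, missing gene/sample, NA).

    zscore mode: value < ``zscore_cutoff`` (strict; Z = -2.0 exactly is
    NOT underexpressed).  ccle_log2 mode: value < ``ccle_log2_cutoff``
    (strict; log2 = 5.0 exactly is NOT underexpressed).
    """
    mode = bundle.study.expression_mode
    if mode == "none" or bundle.expr is None:
        return None
    gene = normalize_symbol(gene)
    if gene not in bundle.expr.index or sample not in bundle.expr.columns:
        return None
    value = bundle.expr.at[gene, sample]
    if not np.isfinite(value):
        return None
    cutoff = thresholds.zscore_cutoff if mode == "zscore" else thresholds.ccle_log2_cutoff
    return bool(value < cutoff)


def lower_quartile_upper_limit(values) -> float:
    """25th percentile (linear interpolation) of the finite values.

    Diagnostic helper for choosing or checking a data-driven log2
    underexpression cutoff on probe-level panels; requires at least four
    finite values.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError(f"need >=4 finite values, got {arr.size}")
    return float(np.percentile(arr, 25))
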
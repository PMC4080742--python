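"""Tissue-specificity and gene-essentiality annotations.

Two small gene-keyed lookup tables provide the biological context the
caller and scorer use:

* a tissue map listing, for tissue-specific genes only, the tissues where
  the gene is expressed (genes absent from the map are treated as
  ubiquitously expressed);
* an essentiality map listing, per gene, the model organisms in which the
  gene (directly or via a pre-mapped homologue) is known to be essential.
  A gene is called essential if it appears for at least one organism.

``expected_expressed`` encodes the tissue-aware rule: a tissue-specific
gene is expected to be expressed only in studies of a matching tissue;
when the study tissue is unknown the conservative answer is True, because
non-expression cannot be excluded.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .geneset_ingest import normalize_symbol

log = logging.getLogger(__name__)

TissueMap = dict[str, frozenset[str]]
EssentialMap = dict[str, frozenset[str]]


def _normalize_tissue(label: str) -> str:
    return label.strip().lower()


def _read_two_column(path: str | Path, key_col: str, value_col: str) -> dict[str, frozenset[str]]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return {}
    missing = [c for c in (key_col, value_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        gene = normalize_symbol(str(getattr(row, key_col)))
        value = _normalize_tissue(str(getattr(row, value_col)))
        if gene and value:
            out.setdefault(gene, set()).add(value)
    return {g: frozenset(v) for g, v in out.items()}


def read_tissue_map(path: str | Path) -> TissueMap:
    """Read a ``gene_symbol TAB tissue`` TSV (header required) into a map.

    Multiple rows per gene accumulate tissues.  Genes absent from the file
    are implicitly non-tissue-specific (ubiquitous); an empty file means
    every gene is treated as ubiquitous.
    """
    tmap = _read_two_column(path, "gene_symbol", "tissue")
    log.info("tissue: %d tissue-specific genes from %s", len(tmap), path)
    return tmap


def expected_expressed(gene: str, study_tissue: str | None, tmap: TissueMap) -> bool:
    """Is ``gene`` expected to be expressed in a study of ``study_tissue``?

    True when the gene is not tissue-specific, when the study tissue is
    among the gene's tissues, or when the study tissue is unknown
    (``None``) -- the conservative default, since expression cannot be
    ruled out without a tissue.
    """
    tissues = tmap.get(normalize_symbol(gene))
    if tissues is None:
        return True
    if study_tissue is None:
        return True
    return _normalize_tissue(study_tissue) in tissues


def read_essential_map(path: str | Path) -> EssentialMap:
    """Read a ``gene_symbol TAB organism`` TSV into an essentiality map.

    The table is expected to be pre-mapped to human symbols (homologue
    resolution done upstream); organism labels are retained for reference.
    """
    emap = _read_two_column(path, "gene_symbol", "organism")
    log.info("essential: %d essential genes from %s", len(emap), path)
    return emap


def is_essential(gene: str, emap: EssentialMap) -> bool:
    """True iff the gene has an essentiality call in at least one organism."""
    return normalize_symbol(gene) in emap
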
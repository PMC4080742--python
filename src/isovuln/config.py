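"""Cohort-level configuration, validation and run manifests.

A cohort config is a YAML file naming the shared inputs (gene-set GMT,
drug TSV, optional tissue and essentiality TSVs), the per-study matrix
files, threshold overrides and the partner-coverage rule.  Relative paths
are resolved against the config file's directory.  Example::

    gene_sets: sets.gmt
    drugs: drugs.tsv
    tissue: tissue.tsv          # optional
    essential: essential.tsv    # optional
    partner_rule: all           # all | any
    thresholds:
      zscore_cutoff: -2.0
    studies:
      - study_id: GBM
        tissue: brain
        sample_class: tumor
        expression_mode: zscore
        cna: cna_GBM.tsv
        expression: expr_GBM.tsv

Validation collects ALL failures (missing files, bad enum values,
cross-field problems such as a zscore study without an expression path)
rather than stopping at the first.  Run manifests record a SHA-256 hash
of every input plus the effective thresholds, so identical inputs yield
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .genomic_profiles import (
    EXPRESSION_MODES,
    SAMPLE_CLASSES,
    StudyConfig,
    Thresholds,
)
from .vulnerability_engine import PARTNER_RULES

log = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Parsed cohort configuration with absolute input paths."""

    gene_sets: str
    drugs: str
    studies: list[StudyConfig] = field(default_factory=list)
    tissue: Optional[str] = None
    essential: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    partner_rule: str = "all"


def _resolve(base: Path, p: Optional[str]) -> Optional[str]:
    if p is None:
        return None
    path = Path(p)
    return str(path if path.is_absolute() else base / path)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Load a cohort YAML; relative paths resolve against its directory."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    thr_kwargs = raw.get("thresholds") or {}
    valid = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(thr_kwargs) - valid
    if unknown:
        raise ValueError(f"{path}: unknown threshold key(s) {sorted(unknown)}")
    studies = []
    for s in raw.get("studies") or []:
        studies.append(
            StudyConfig(
                study_id=str(s.get("study_id", "")),
                tissue=s.get("tissue"),
                sample_class=s.get("sample_class", "tumor"),
                expression_mode=s.get("expression_mode", "none"),
                cna_path=_resolve(base, s.get("cna")),
                expr_path=_resolve(base, s.get("expression")),
            )
        )
    return CohortConfig(
        gene_sets=_resolve(base, raw.get("gene_sets")) or "",
        drugs=_resolve(base, raw.get("drugs")) or "",
        tissue=_resolve(base, raw.get("tissue")),
        essential=_resolve(base, raw.get("essential")),
        thresholds=Thresholds(**thr_kwargs),
        partner_rule=raw.get("partner_rule", "all"),
        studies=studies,
    )


def _check_matrix_header(path: str) -> Optional[str]:
    try:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
    except OSError as exc:
        return f"unreadable matrix {path}: {exc}"
    if len(header) < 2:
        return f"matrix {path}: header has no sample columns"
    return None


def validate_config(config: CohortConfig) -> list[str]:
    """Check a cohort config; returns the list of ALL failures (empty = ok)."""
    failures: list[str] = []

    def need_file(label: str, p: Optional[str], required: bool) -> bool:
        if not p:
            if required:
                failures.append(f"{label}: path missing")
            return False
        if not Path(p).is_file():
            failures.append(f"{label}: file not found: {p}")
            return False
        return True

    need_file("gene_sets", config.gene_sets, required=True)
    need_file("drugs", config.drugs, required=True)
    if config.tissue:
        need_file("tissue", config.tissue, required=False)
    if config.essential:
        need_file("essential", config.essential, required=False)
    if config.partner_rule not in PARTNER_RULES:
        failures.append(
            f"partner_rule: must be one of {PARTNER_RULES}, got {config.partner_rule!r}"
        )
    for t in ("zscore_cutoff", "ccle_log2_cutoff"):
        if not isinstance(getattr(config.thresholds, t), (int, float)):
            failures.append(f"thresholds.{t}: not numeric")
    for t in ("max_set_size", "max_drug_targets"):
        if getattr(config.thresholds, t) < 1:
            failures.append(f"thresholds.{t}: must be >= 1")
    if not config.studies:
        failures.append("studies: none configured")
    seen_ids: set[str] = set()
    for s in config.studies:
        label = f"study {s.study_id or '<unnamed>'}"
        if not s.study_id:
            failures.append(f"{label}: study_id missing")
        elif s.study_id in seen_ids:
            failures.append(f"{label}: duplicate study_id")
        seen_ids.add(s.study_id)
        if need_file(f"{label}: cna", s.cna_path, required=True):
            err = _check_matrix_header(s.cna_path)
            if err:
                failures.append(f"{label}: {err}")
        if s.expression_mode != "none":
            if need_file(f"{label}: expression", s.expr_path, required=True):
                err = _check_matrix_header(s.expr_path)
                if err:
                    failures.append(f"{label}: {err}")
    return failures


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: CohortConfig, version: str) -> dict:
    """Input hashes + effective settings; deterministic for identical inputs."""
    inputs: dict[str, str] = {}
    paths = [("gene_sets", config.gene_sets), ("drugs", config.drugs),
             ("tissue", config.tissue), ("essential", config.essential)]
    for s in config.studies:
        paths.append((f"cna:{s.study_id}", s.cna_path))
        paths.append((f"expression:{s.study_id}", s.expr_path))
    for label, p in paths:
        if p and Path(p).is_file():
            inputs[label] = sha256_file(p)
    return {
        "tool": "isovuln",
        "version": version,
        "partner_rule": config.partner_rule,
        "thresholds": dataclasses.asdict(config.thresholds),
        "inputs": dict(sorted(inputs.items())),
    }


def write_manifest(manifest: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir) / "manifest.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
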
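"""Cohort-level aggregation and machine-readable reports.

Aggregates scored vulnerabilities into:

* deletion events -- distinct (gene set, deleted gene) pairs, the unit on
  which tumor <-> cell-line matching is counted (a vulnerability whose
  set lost two members fans out into two events);
* a cohort summary -- vulnerability and sample counts, the score
  histogram, the fractions of vulnerabilities with an FDA-approved /
  cancer drug, the fraction whose every exploit option hits an essential
  gene, and a per-study breakdown.

Writers emit a vulnerabilities TSV (one row per call), a summary JSON and
a per-study TSV; the TSV round-trips through :func:`read_vulnerabilities`
so that re-reading reproduces the summary exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .vulnerability_engine import Criteria, Vulnerability

log = logging.getLogger(__name__)

TSV_COLUMNS = (
    "study_id",
    "sample_id",
    "sample_class",
    "set_id",
    "reaction_name",
    "deleted_genes",
    "intact_members",
    "expected_expressed_partners",
    "exploit_map",
    "suggested_drugs",
    "single_drug_covers_all_partners",
    "underexpressed_deletion",
    "has_fda_drug",
    "has_cancer_drug",
    "nonessential_target",
    "score",
)


@dataclass(frozen=True)
class DeletionEvent:
    """A distinct (gene set, deleted gene) pair and where it was observed.

    Samples are keyed (study_id, sample_id) and partitioned by sample
    class; an event exists only if observed in at least one sample.
    """

    set_id: str
    deleted_gene: str
    tumor_samples: frozenset[tuple[str, str]] = frozenset()
    cell_line_samples: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not (self.tumor_samples or self.cell_line_samples):
            raise ValueError("deletion event observed in no sample")


@dataclass
class CohortSummary:
    """Aggregate statistics over a scored cohort (all fractions in [0,1])."""

    n_vulnerabilities: int
    n_vulnerable_tumor_samples: int
    n_vulnerable_cell_lines: int
    n_deletion_events: int
    n_tumor_events: int
    fraction_tumor_events_with_cell_line_match: Optional[float]
    score_histogram: dict[int, int]
    fraction_with_fda_drug: Optional[float]
    fraction_with_cancer_drug: Optional[float]
    fraction_targeting_essential: Optional[float]
    per_study: dict[str, dict[str, int]]


def deletion_events(
    vulns: Sequence[Vulnerability], key: str = "set_and_gene"
) -> list[DeletionEvent]:
    """Fan scored vulnerabilities out into distinct deletion events.

    The default event key is (set_id, deleted_gene); ``key='gene'``
    collapses across sets (sensitivity-analysis alternative).  A
    vulnerability with several deleted genes contributes one event per
    gene.  Output is sorted by (set_id, gene).
    """
    if key not in ("set_and_gene", "gene"):
        raise ValueError(f"unknown event key {key!r}")
    acc: dict[tuple[str, str], dict[str, set]] = {}
    for v in vulns:
        for gene in v.deleted_genes:
            k = (v.set_id if key == "set_and_gene" else "", gene)
            slot = acc.setdefault(k, {"tumor": set(), "cell_line": set()})
            slot[v.sample_class].add((v.study_id, v.sample_id))
    return [
        DeletionEvent(
            set_id=set_id,
            deleted_gene=gene,
            tumor_samples=frozenset(slot["tumor"]),
            cell_line_samples=frozenset(slot["cell_line"]),
        )
        for (set_id, gene), slot in sorted(acc.items())
    ]


def match_rate(events: Sequence[DeletionEvent]) -> Optional[float]:
    """Among events seen in >=1 tumor sample, the fraction also seen in
    >=1 cell line; None when no tumor events exist."""
    tumor_events = [e for e in events if e.tumor_samples]
    if not tumor_events:
        return None
    matched = sum(1 for e in tumor_events if e.cell_line_samples)
    return matched / len(tumor_events)


def summarize(vulns: Sequence[Vulnerability], event_key: str = "set_and_gene") -> CohortSummary:
    """Compute the cohort summary from scored vulnerabilities."""
    for v in vulns:
        if v.criteria is None or v.score is None:
            raise ValueError(
                f"unscored vulnerability {v.study_id}/{v.sample_id}/{v.set_id}"
            )
    events = deletion_events(vulns, key=event_key)
    tumor_events = [e for e in events if e.tumor_samples]
    samples = {(v.study_id, v.sample_id, v.sample_class) for v in vulns}
    hist = {s: 0 for s in range(5)}
    for v in vulns:
        hist[v.score] += 1
    n = len(vulns)
    per_study: dict[str, dict[str, int]] = {}
    for v in vulns:
        slot = per_study.setdefault(
            v.study_id, {"n_vulnerabilities": 0, "n_vulnerable_samples": 0}
        )
        slot["n_vulnerabilities"] += 1
    for study_id in per_study:
        per_study[study_id]["n_vulnerable_samples"] = len(
            {s for s in samples if s[0] == study_id}
        )
    return CohortSummary(
        n_vulnerabilities=n,
        n_vulnerable_tumor_samples=len([s for s in samples if s[2] == "tumor"]),
        n_vulnerable_cell_lines=len([s for s in samples if s[2] == "cell_line"]),
        n_deletion_events=len(events),
        n_tumor_events=len(tumor_events),
        fraction_tumor_events_with_cell_line_match=match_rate(events),
        score_histogram=hist,
        fraction_with_fda_drug=(
            sum(v.criteria.has_fda_drug for v in vulns) / n if n else None
        ),
        fraction_with_cancer_drug=(
            sum(v.criteria.has_cancer_drug for v in vulns) / n if n else None
        ),
        fraction_targeting_essential=(
            sum(not v.criteria.nonessential_target for v in vulns) / n if n else None
        ),
        per_study=dict(sorted(per_study.items())),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _fmt_exploit_map(v: Vulnerability) -> str:
    return ";".join(f"{p}:{'|'.join(ds)}" for p, ds in v.exploit_map)


def _parse_exploit_map(text: str) -> tuple[tuple[str, tuple[str, ...]], ...]:
    if not text:
        return ()
    out = []
    for chunk in text.split(";"):
        partner, _, ds = chunk.partition(":")
        out.append((partner, tuple(d for d in ds.split("|") if d)))
    return tuple(out)


def write_vulnerabilities(vulns: Sequence[Vulnerability], path: str | Path) -> None:
    """Write scored vulnerabilities as a TSV, one row per call."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for v in vulns:
            if v.criteria is None:
                raise ValueError("cannot serialize an unscored vulnerability")
            row = [
                v.study_id,
                v.sample_id,
                v.sample_class,
                v.set_id,
                v.reaction_name,
                ";".join(v.deleted_genes),
                ";".join(v.intact_members),
                ";".join(v.expected_expressed_partners),
                _fmt_exploit_map(v),
                ";".join(v.suggested_drugs),
                str(int(v.single_drug_covers_all_partners)),
                str(int(v.criteria.underexpressed_deletion)),
                str(int(v.criteria.has_fda_drug)),
                str(int(v.criteria.has_cancer_drug)),
                str(int(v.criteria.nonessential_target)),
                str(v.score),
            ]
            fh.write("\t".join(row) + "\n")


def read_vulnerabilities(path: str | Path) -> list[Vulnerability]:
    """Read a vulnerabilities TSV back; inverse of :func:`write_vulnerabilities`."""
    out: list[Vulnerability] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(TSV_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(TSV_COLUMNS)} fields")
            rec = dict(zip(TSV_COLUMNS, f))
            criteria = Criteria(
                underexpressed_deletion=rec["underexpressed_deletion"] == "1",
                has_fda_drug=rec["has_fda_drug"] == "1",
                has_cancer_drug=rec["has_cancer_drug"] == "1",
                nonessential_target=rec["nonessential_target"] == "1",
            )
            out.append(
                Vulnerability(
                    study_id=rec["study_id"],
                    sample_id=rec["sample_id"],
                    sample_class=rec["sample_class"],
                    set_id=rec["set_id"],
                    reaction_name=rec["reaction_name"],
                    deleted_genes=tuple(rec["deleted_genes"].split(";")),
                    intact_members=tuple(
                        g for g in rec["intact_members"].split(";") if g
                    ),
                    expected_expressed_partners=tuple(
                        g for g in rec["expected_expressed_partners"].split(";") if g
                    ),
                    exploit_map=_parse_exploit_map(rec["exploit_map"]),
                    suggested_drugs=tuple(
                        d for d in rec["suggested_drugs"].split(";") if d
                    ),
                    single_drug_covers_all_partners=(
                        rec["single_drug_covers_all_partners"] == "1"
                    ),
                    criteria=criteria,
                    score=int(rec["score"]),
                )
            )
    return out


def _round4(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(x, 4)


def summary_to_dict(summary: CohortSummary) -> dict:
    """JSON-ready dict; fractions rounded to 4 decimals."""
    return {
        "n_vulnerabilities": summary.n_vulnerabilities,
        "n_vulnerable_tumor_samples": summary.n_vulnerable_tumor_samples,
        "n_vulnerable_cell_lines": summary.n_vulnerable_cell_lines,
        "n_deletion_events": summary.n_deletion_events,
        "n_tumor_events": summary.n_tumor_events,
        "fraction_tumor_events_with_cell_line_match": _round4(
            summary.fraction_tumor_events_with_cell_line_match
        ),
        "score_histogram": {str(k): v for k, v in sorted(summary.score_histogram.items())},
        "fraction_with_fda_drug": _round4(summary.fraction_with_fda_drug),
        "fraction_with_cancer_drug": _round4(summary.fraction_with_cancer_drug),
        "fraction_targeting_essential": _round4(summary.fraction_targeting_essential),
        "per_study": summary.per_study,
    }


def write_reports(
    summary: CohortSummary, vulns: Sequence[Vulnerability], out_dir: str | Path
) -> dict[str, Path]:
    """Write vulnerabilities.tsv, summary.json and per_study.tsv under
    ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vulnerabilities": out / "vulnerabilities.tsv",
        "summary": out / "summary.json",
        "per_study": out / "per_study.tsv",
    }
    write_vulnerabilities(vulns, paths["vulnerabilities"])
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary_to_dict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["per_study"], "w", encoding="utf-8") as fh:
        fh.write("study_id\tn_vulnerabilities\tn_vulnerable_samples\n")
        for study_id, rec in summary.per_study.items():
            fh.write(
                f"{study_id}\t{rec['n_vulnerabilities']}\t{rec['n_vulnerable_samples']}\n"
            )
    log.info(
        "reports: %d vulnerabilities, %d deletion events written to %s",
        summary.n_vulnerabilities, summary.n_deletion_events, out,
    )
    return paths
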
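"""End-to-end orchestration: evidence → NME/Nat calls → motif statistics
→ physicochemistry → summary report and artifact files.

Two modes exist.  In *sequence* mode a FASTA of precursors accompanies
the evidence, every record is anchored against its precursor and
inconsistencies are detected.  In *nterm-only* mode (the default when no
FASTA is supplied — the packaged evidence table carries no full
sequences) classification uses the observed N-terminus alone, assuming
the canonical nuclear-encoded Met start.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import PipelineConfig
from .errors import InputError
from .io import (
    AcetylationEvidence,
    ProteinRecord,
    read_evidence_tsv,
    read_fasta,
    write_calls_tsv,
    write_report_json,
)
from .motifs import build_pfm, scan_accoa_motif, write_motif_hits_tsv
from .physchem import acidity_profile, tio2_enrichable
from .rules import (
    NatAssignment,
    NmeStatus,
    NmeStatusKind,
    ParsedNTerm,
    SummaryReport,
    assign_nat,
    attach_physchem_aggregates,
    classify_from_nterm_only,
    classify_nme_status,
    summarize,
)

logger = logging.getLogger("ntproc")


def parsed_from_evidence(ev: AcetylationEvidence) -> ParsedNTerm:
    """Rebuild the parsed N-terminus carried by an evidence record."""
    flags = tuple(i + 1 in ev.phospho_positions
                  for i in range(len(ev.residues)))
    return ParsedNTerm(tuple(ev.residues), ev.acetylated, flags)


@dataclass
class PipelineResult:
    """Everything one run produces, before/besides file artifacts."""

    report: SummaryReport
    calls: list[dict]
    statuses: list[NmeStatus]
    assignments: list[Optional[NatAssignment]]
    artifacts: dict = field(default_factory=dict)


def run_pipeline(
    evidence_path: str | Path,
    fasta_path: Optional[str | Path] = None,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the full annotation pipeline on an evidence table.

    Writes, when ``out_dir`` is given: per-protein ``calls.tsv``, PFM
    tables for the two groups, ``motif_hits.tsv`` (sequence mode only)
    and ``report.json``.  The report payload is deterministic: identical
    inputs and config give byte-identical JSON.
    """
    config = config or PipelineConfig()
    evidence = read_evidence_tsv(evidence_path)

    proteins: dict[str, ProteinRecord] = {}
    mode = config.mode
    if mode == "auto":
        mode = "sequence" if fasta_path else "nterm-only"
    if mode == "sequence":
        if fasta_path is None:
            raise InputError("sequence mode requires a FASTA file")
        proteins = {p.id: p for p in read_fasta(fasta_path)}
        missing = [ev.protein_id for ev in evidence
                   if ev.protein_id not in proteins]
        if missing:
            raise InputError(
                f"evidence protein id(s) not in FASTA: {sorted(set(missing))}"
            )
    logger.info("mode=%s, %d evidence records", mode, len(evidence))

    statuses: list[NmeStatus] = []
    assignments: list[Optional[NatAssignment]] = []
    for ev in evidence:
        parsed = parsed_from_evidence(ev)
        if mode == "sequence":
            status = classify_nme_status(proteins[ev.protein_id], parsed)
        else:
            status = classify_from_nterm_only(parsed)
        nat = (assign_nat(parsed, status)
               if status.status is not NmeStatusKind.INCONSISTENT else None)
        statuses.append(status)
        assignments.append(nat)

    model = config.ionizable_model().acetylated()
    thresholds = config.thresholds()
    calls: list[dict] = []
    for ev, status, nat in zip(evidence, statuses, assignments):
        profile = acidity_profile(ev.residues,
                                  n_phospho=len(ev.phospho_positions),
                                  model=model)
        enrichable, reason = tio2_enrichable(ev, profile, thresholds)
        group = {
            NmeStatusKind.NME_INDEPENDENT: "i",
            NmeStatusKind.NME_DEPENDENT: "ii",
            NmeStatusKind.INCONSISTENT: "inconsistent",
        }[status.status]
        calls.append({
            "protein_id": ev.protein_id,
            "group": group,
            "exposed_residue": status.exposed_residue or "",
            "nat_call": nat.label() if nat is not None else "",
            "rule_id": (nat.rule_id or "R5") if nat is not None else "",
            "pI": round(profile.pI, 3) if profile.pI is not None else None,
            "acidic_count": profile.acidic_count,
            "enrichable": enrichable,
            "reason": reason or "",
        })

    report = summarize(evidence, list(zip(statuses, assignments)))
    attach_physchem_aggregates(report, calls)
    cfg_echo = config.to_dict()
    cfg_echo["resolved_mode"] = mode
    report.config = cfg_echo
    result = PipelineResult(report, calls, statuses, assignments)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_calls_tsv(calls, out / "calls.tsv")
        group_i = [ev.residues for ev, st in zip(evidence, statuses)
                   if st.status is NmeStatusKind.NME_INDEPENDENT]
        group_ii = [ev.residues for ev, st in zip(evidence, statuses)
                    if st.status is NmeStatusKind.NME_DEPENDENT]
        build_pfm(group_i, config.pfm_length).to_tsv(out / "pfm_group_i.tsv")
        build_pfm(group_ii, config.pfm_length).to_tsv(out / "pfm_group_ii.tsv")
        result.artifacts["calls"] = out / "calls.tsv"
        result.artifacts["pfm_group_i"] = out / "pfm_group_i.tsv"
        result.artifacts["pfm_group_ii"] = out / "pfm_group_ii.tsv"
        if mode == "sequence":
            hits = [h for p in proteins.values() for h in scan_accoa_motif(p)]
            write_motif_hits_tsv(hits, out / "motif_hits.tsv")
            result.artifacts["motif_hits"] = out / "motif_hits.tsv"
        write_report_json(report.to_dict(), out / "report.json")
        result.artifacts["report"] = out / "report.json"
    return result


# -- validation against annotations ----------------------------------------

def _annotation_to_set(label: str) -> frozenset[str]:
    label = label.strip()
    if not label or label.lower() == "unassigned":
        return frozenset()
    return frozenset(part.strip() for part in label.replace("or ", "").split(",")
                     if part.strip())


@dataclass
class AgreementTable:
    """Per-record comparison of rule-engine calls with source annotations."""

    rows: list[dict]

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_match(self) -> int:
        return sum(1 for r in self.rows if r["match"])

    @property
    def agreement(self) -> float:
        return self.n_match / self.n_total if self.rows else 0.0

    def confusion(self) -> dict[tuple[str, str], int]:
        """(annotated label, called label) → count; diagonal iff all agree."""
        table: dict[tuple[str, str], int] = {}
        for r in self.rows:
            key = (r["annotated"], r["called"])
            table[key] = table.get(key, 0) + 1
        return table


def validate_against_annotations(
    assignments: Sequence[Optional[NatAssignment]],
    evidence: Sequence[AcetylationEvidence],
) -> AgreementTable:
    """Compare rule-engine Nat calls with the evidence table's own column.

    An ambiguous annotation such as ``"NatC, or NatE, or NatF"`` matches
    iff the called candidate set equals the annotated set.
    """
    if len(assignments) != len(evidence):
        raise InputError("one assignment per evidence record required")
    missing = [ev.protein_id for ev in evidence if ev.nat_annotation is None]
    if missing:
        raise InputError(
            f"records without nat_annotation: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    rows = []
    for nat, ev in zip(assignments, evidence):
        annotated = _annotation_to_set(ev.nat_annotation or "")
        called = nat.candidates if nat is not None else frozenset()
        rows.append({
            "protein_id": ev.protein_id,
            "annotated": " | ".join(sorted(annotated)) or "unassigned",
            "called": " | ".join(sorted(called)) or "unassigned",
            "match": annotated == called,
        })
    return AgreementTable(rows)


def configure_logging(verbose: bool = False) -> None:
    """Log to standard error; the report files stay machine-readable."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
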
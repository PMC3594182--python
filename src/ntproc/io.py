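"""Reading and writing the pipeline's external formats.

Protein sequences travel as FASTA (parsed with Biopython), acetylation
evidence as a tab-separated table with one row per protein carrying the
modified N-terminus in the three-letter ``Ac-Met-Glu-Thr-`` dialect, and
summary reports as JSON plus a companion per-protein calls TSV.

The package ships a transcription of the study's evidence table
(58 N-terminally acetylated poplar proteins) accessible via
:func:`load_table1_evidence`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import ParseError, SchemaError, ValidationError

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes rejected unless permissive mode is on.
AMBIGUOUS_AA = frozenset("BJOUXZ")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier.

    The sequence is the full precursor as encoded by the nuclear gene,
    i.e. it starts with the initiator Met for every canonical record.
    With ``permissive=True`` the ambiguity code X is tolerated; such
    positions are excluded from downstream statistics by the callers.
    """

    id: str
    sequence: str
    description: str = ""
    permissive: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        allowed = STANDARD_AA | {"X"} if self.permissive else STANDARD_AA
        bad = set(self.sequence) - allowed
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AcetylationEvidence:
    """One observed acetylated N-terminus — the pipeline's atomic input.

    ``residues`` is the parsed one-letter form of ``nterm_label``;
    ``phospho_positions`` are 1-based positions within the observed
    peptide.  ``nat_annotation`` is the source table's expected Nat call,
    carried along for validation only and never consulted by the rules.
    """

    protein_id: str
    nterm_label: str
    residues: list[str]
    acetylated: bool = True
    phospho_positions: list[int] = field(default_factory=list)
    nat_annotation: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValidationError(
                f"evidence {self.protein_id!r}: need at least 2 parsed residues"
            )
        for pos in self.phospho_positions:
            if not (1 <= pos <= len(self.residues)):
                raise ValidationError(
                    f"evidence {self.protein_id!r}: phospho position {pos} "
                    f"outside peptide of length {len(self.residues)}"
                )
            if self.residues[pos - 1] not in "STY":
                raise ValidationError(
                    f"evidence {self.protein_id!r}: phospho position {pos} "
                    f"is {self.residues[pos - 1]}, expected S, T or Y"
                )


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and record order is preserved.  With
    ``permissive=True`` the ambiguity code X is tolerated (such records
    are excluded from downstream statistics by the callers that care).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(
            ProteinRecord(rec.id, seq, rec.description, permissive=permissive)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# -- evidence TSV -----------------------------------------------------------

_MANDATORY_COLUMNS = ("protein_id", "nterm_label")


def read_evidence_tsv(path: str | Path) -> list[AcetylationEvidence]:
    """Read the acetylation-evidence table.

    Tab-separated, UTF-8, ``#`` comment lines ignored, header required
    with at least ``protein_id`` and ``nterm_label`` columns.  Optional
    columns: ``phospho_positions`` (comma-separated 1-based integers),
    ``nat_annotation`` and ``description``.
    """
    from .rules import parse_nterm  # deferred to avoid a cycle

    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    reader = csv.DictReader(lines, delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in _MANDATORY_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    out: list[AcetylationEvidence] = []
    for i, row in enumerate(reader, start=2):
        label = (row.get("nterm_label") or "").strip()
        try:
            parsed = parse_nterm(label)
        except (ParseError, ValidationError) as exc:
            raise ParseError(f"{path}, row {i}: {exc}") from exc
        raw_pp = (row.get("phospho_positions") or "").strip()
        positions = [int(tok) for tok in raw_pp.split(",") if tok.strip()]
        # markers inside the label itself also contribute
        for j, flag in enumerate(parsed.phospho_flags, start=1):
            if flag and j not in positions:
                positions.append(j)
        annotation = (row.get("nat_annotation") or "").strip() or None
        out.append(
            AcetylationEvidence(
                protein_id=(row.get("protein_id") or "").strip(),
                nterm_label=label,
                residues=list(parsed.residues),
                acetylated=parsed.acetylated,
                phospho_positions=sorted(positions),
                nat_annotation=annotation,
                description=(row.get("description") or "").strip(),
            )
        )
    return out


def write_evidence_tsv(evidence: Iterable[AcetylationEvidence],
                       path: str | Path) -> None:
    """Write evidence records in the dialect :func:`read_evidence_tsv` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tdescription\tnterm_label\t"
                 "phospho_positions\tnat_annotation\n")
        for ev in evidence:
            pp = ",".join(str(p) for p in ev.phospho_positions)
            fh.write(f"{ev.protein_id}\t{ev.description}\t{ev.nterm_label}\t"
                     f"{pp}\t{ev.nat_annotation or ''}\n")


def load_table1_evidence() -> list[AcetylationEvidence]:
    """Load the packaged evidence fixture (58 acetylated poplar proteins)."""
    with resources.as_file(
        resources.files("ntproc.data").joinpath("table1_evidence.tsv")
    ) as p:
        return read_evidence_tsv(p)


# -- report serialization ---------------------------------------------------

def write_report_json(report_dict: dict, path: str | Path) -> None:
    """Serialize a report with stable key order (insertion order kept)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_dict, fh, indent=2)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


CALLS_COLUMNS = ("protein_id", "group", "exposed_residue", "nat_call",
                 "rule_id", "pI", "acidic_count", "enrichable", "reason")


def write_calls_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Write the per-protein calls table (one row per evidence record)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in CALLS_COLUMNS) + "\n")
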
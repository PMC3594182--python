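"""Co-translational N-terminal processing rules.

Nuclear-encoded eukaryotic proteins start with an initiator Met (iMet).
Methionine aminopeptidases (MAPs) excise the iMet when the second residue
has a small side chain — Ala, Val, Ser, Thr, Cys, Gly or Pro (the NME
rule).  N-terminal acetyltransferases (Nats) then acetylate the free
α-amino group; which Nat acts is determined by the N-terminal sequence:

* **NatA** — small residues (Ser, Ala, Thr, Val, Gly, Cys) exposed by NME;
* **NatB** — retained iMet followed by Asp, Glu or Asn;
* **NatC / NatE / NatF** (redundant in vitro) — retained iMet followed by
  the hydrophobic residues Leu, Ile or Phe;
* **NatF** alone — retained iMet followed by a small residue that the NME
  rule would normally have licensed for excision (e.g. Met-Gly-);
* **NatD** — histone-specific; no activity was observed in the study this
  package models, so it is deliberately never emitted.

Observed acetylated N-termini therefore split into two groups:
**group (i)**, NME-independent (acetylated residue is the retained iMet,
precursor position 1), and **group (ii)**, NME-dependent (acetylated
residue is the one exposed at precursor position 2 after Met excision).

This module parses the evidence dialect (``Ac-Met-Glu-Thr-``), classifies
NME status with or without the full precursor sequence, predicts Met
excision from a precursor, assigns candidate Nat types by an ordered rule
table, and aggregates per-protein calls into a summary report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Optional, Sequence

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

from .errors import InputError, ParseError
from .io import AcetylationEvidence, ProteinRecord

#: Residues whose exposure at position 2 licenses initiator-Met excision.
NME_SMALL_RESIDUES = frozenset("AVSTCGP")

#: NatA substrates: small residues exposed by NME (note: no Pro).
NATA_SUBSTRATES = frozenset("SATVGC")

#: NatB substrates: second residue behind a retained iMet.
NATB_SECOND_RESIDUES = frozenset("DEN")

#: NatC/NatE/NatF (redundant) substrates: hydrophobic second residue.
NATCEF_SECOND_RESIDUES = frozenset("LIF")

#: Retained-iMet + small residue: NatF alone.
NATF_SECOND_RESIDUES = NATA_SUBSTRATES

ALL_NAT_TYPES = ("NatA", "NatB", "NatC", "NatD", "NatE", "NatF")


class NmeStatusKind(str, Enum):
    """NME-dependence of an observed acetylated N-terminus."""

    NME_INDEPENDENT = "NME_INDEPENDENT"  # group (i): acetylated iMet retained
    NME_DEPENDENT = "NME_DEPENDENT"      # group (ii): acetylation at position 2
    INCONSISTENT = "INCONSISTENT"        # evidence does not anchor to precursor


@dataclass(frozen=True)
class ParsedNTerm:
    """A parsed modified N-terminus from the evidence dialect."""

    residues: tuple[str, ...]
    acetylated: bool
    phospho_flags: tuple[bool, ...]

    def render(self) -> str:
        """Re-render in the three-letter dialect; inverse of :func:`parse_nterm`."""
        parts = []
        for aa, phos in zip(self.residues, self.phospho_flags):
            token = protein_letters_1to3[aa]
            if phos:
                token += "(p)"
            parts.append(token)
        prefix = "Ac-" if self.acetylated else ""
        return prefix + "-".join(parts) + "-"


@dataclass(frozen=True)
class NmeStatus:
    """NME classification of one observed N-terminus."""

    status: NmeStatusKind
    exposed_residue: Optional[str] = None
    position_in_precursor: Optional[int] = None


@dataclass(frozen=True)
class NatAssignment:
    """Candidate Nat types plus the rule that produced them."""

    candidates: frozenset[str]
    rule_id: Optional[str]

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    @property
    def unassigned(self) -> bool:
        return not self.candidates

    def label(self) -> str:
        """Human-readable call, matching the evidence table's annotation style."""
        if self.unassigned:
            return "unassigned"
        return ", or ".join(sorted(self.candidates))


def parse_nterm(label: str) -> ParsedNTerm:
    """Parse a modified-N-terminus string such as ``"Ac-Met-Glu-Thr-"``.

    The label is a dash-joined list of three-letter residue codes
    (case-insensitive), optionally prefixed ``Ac-`` for Nα-acetylation,
    optionally ending with a dash; a residue token may carry a ``(p)``
    suffix marking phosphorylation of that residue.
    """
    text = label.strip()
    if not text:
        raise ParseError("empty N-terminus label")
    acetylated = False
    if text.lower().startswith("ac-"):
        acetylated = True
        text = text[3:]
    tokens = [t for t in text.split("-") if t]
    residues: list[str] = []
    phospho: list[bool] = []
    for token in tokens:
        phos = False
        if token.lower().endswith("(p)"):
            phos = True
            token = token[:-3]
        key = token.capitalize()
        if key not in protein_letters_3to1:
            raise ParseError(f"unknown residue code {token!r} in {label!r}")
        residues.append(protein_letters_3to1[key])
        phospho.append(phos)
    if len(residues) < 2:
        raise ParseError(
            f"label {label!r} has {len(residues)} residue(s); need at least 2"
        )
    return ParsedNTerm(tuple(residues), acetylated, tuple(phospho))


def classify_nme_status(protein: ProteinRecord, parsed: ParsedNTerm) -> NmeStatus:
    """Classify NME status by anchoring the observed peptide to its precursor.

    If the observed residues match precursor positions 1..k the acetylated
    residue is the retained iMet (group i).  If the precursor starts with
    Met and the observed residues match positions 2..k+1, the Met was
    excised and the acetylated residue sits at precursor position 2
    (group ii).  Anything else is INCONSISTENT.
    """
    k = len(parsed.residues)
    if len(protein.sequence) < k + 1:
        raise InputError(
            f"protein {protein.id!r} shorter than evidence window + 1"
        )
    window = "".join(parsed.residues)
    if protein.sequence[:k] == window:
        return NmeStatus(NmeStatusKind.NME_INDEPENDENT, window[0], 1)
    if protein.sequence[0] == "M" and protein.sequence[1:k + 1] == window:
        return NmeStatus(NmeStatusKind.NME_DEPENDENT, window[0], 2)
    return NmeStatus(NmeStatusKind.INCONSISTENT)


def classify_from_nterm_only(parsed: ParsedNTerm) -> NmeStatus:
    """Classify NME status from the observed N-terminus alone.

    Without the precursor, the canonical nuclear-encoded Met start is
    assumed: an acetylated N-terminal Met is the retained iMet (group i);
    any other acetylated residue is the one exposed at position 2 after
    Met excision (group ii).
    """
    if not parsed.acetylated:
        raise InputError("classification requires an acetylated N-terminus")
    first = parsed.residues[0]
    if first == "M":
        return NmeStatus(NmeStatusKind.NME_INDEPENDENT, "M", 1)
    return NmeStatus(NmeStatusKind.NME_DEPENDENT, first, 2)


def predict_nme(protein: ProteinRecord) -> bool:
    """Predict initiator-Met excision from the precursor sequence.

    True iff position 2 carries a small side chain (Ala, Val, Ser, Thr,
    Cys, Gly or Pro) — the substrate rule of the methionine
    aminopeptidases.
    """
    if len(protein.sequence) < 2:
        raise InputError(f"protein {protein.id!r}: sequence shorter than 2")
    if protein.sequence[0] != "M":
        raise InputError(
            f"protein {protein.id!r}: precursor does not start with Met"
        )
    return protein.sequence[1] in NME_SMALL_RESIDUES


def assign_nat(parsed: ParsedNTerm, status: NmeStatus) -> NatAssignment:
    """Assign candidate Nat types by the ordered substrate rule table.

    R1  NME-dependent, exposed residue ∈ {S,A,T,V,G,C}        → {NatA}
    R2  iMet retained, second residue ∈ {D,E,N}               → {NatB}
    R3  iMet retained, second residue ∈ {L,I,F}               → {NatC,NatE,NatF}
    R4  iMet retained, second residue ∈ {S,A,T,V,G,C}         → {NatF}
    R5  otherwise                                             → unassigned

    The NME status gates the two regimes, so at most one rule fires.
    An exposed Pro after excision falls through to R5: Pro licenses
    excision but is not a recorded Nat substrate.  NatD is never emitted.
    """
    if status.status is NmeStatusKind.INCONSISTENT:
        raise InputError("cannot assign a Nat to an INCONSISTENT N-terminus")
    if not parsed.acetylated:
        raise InputError("Nat assignment requires an acetylated N-terminus")
    if status.status is NmeStatusKind.NME_DEPENDENT:
        exposed = parsed.residues[0]
        if exposed in NATA_SUBSTRATES:
            return NatAssignment(frozenset({"NatA"}), "R1")
        return NatAssignment(frozenset(), None)
    second = parsed.residues[1]
    if second in NATB_SECOND_RESIDUES:
        return NatAssignment(frozenset({"NatB"}), "R2")
    if second in NATCEF_SECOND_RESIDUES:
        return NatAssignment(frozenset({"NatC", "NatE", "NatF"}), "R3")
    if second in NATF_SECOND_RESIDUES:
        return NatAssignment(frozenset({"NatF"}), "R4")
    return NatAssignment(frozenset(), None)


# -- aggregation ------------------------------------------------------------

#: Report keys for the rule-based (headline) Nat tallies.
RULE_COUNT_KEYS = {
    "R1": "NatA",
    "R2": "NatB",
    "R3": "NatCEF_ambiguous",
    "R4": "NatF",
    None: "unassigned",
}


def _aa3(aa: str) -> str:
    return protein_letters_1to3[aa]


@dataclass
class SummaryReport:
    """Aggregated counts over an evidence set.

    ``nat_counts`` tallies by the rule that fired (ambiguous
    NatC/NatE/NatF sets stay their own bucket, never collapsed into a
    single enzyme), which is the accounting the headline percentages
    use.  ``nat_candidate_counts`` additionally counts each protein once
    toward every member of its candidate set, plus an ``ambiguous``
    tally.
    """

    total: int = 0
    n_group_i: int = 0
    n_group_ii: int = 0
    n_inconsistent: int = 0
    nat_counts: dict = field(default_factory=dict)
    nat_candidate_counts: dict = field(default_factory=dict)
    group_i_motif_counts: dict = field(default_factory=dict)
    group_ii_exposed_counts: dict = field(default_factory=dict)
    phospho: dict = field(default_factory=dict)
    physchem: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def percentages(self) -> dict:
        """Derived percentages, rendered to one decimal; never stored."""
        if self.total == 0:
            return {}
        pct = lambda n: round(100.0 * n / self.total, 1)  # noqa: E731
        return {
            "group_i_pct": pct(self.n_group_i),
            "group_ii_pct": pct(self.n_group_ii),
            "phospho_pct": pct(self.phospho.get("n_with_phospho", 0)),
        }

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "n_group_i": self.n_group_i,
            "n_group_ii": self.n_group_ii,
            "n_inconsistent": self.n_inconsistent,
            "nat_counts": dict(self.nat_counts),
            "nat_candidate_counts": dict(self.nat_candidate_counts),
            "group_i_motif_counts": dict(self.group_i_motif_counts),
            "group_ii_exposed_counts": dict(self.group_ii_exposed_counts),
            "phospho": dict(self.phospho),
            "physchem": dict(self.physchem),
            "percentages": self.percentages(),
            "config": dict(self.config),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SummaryReport":
        return cls(
            total=d["total"],
            n_group_i=d["n_group_i"],
            n_group_ii=d["n_group_ii"],
            n_inconsistent=d["n_inconsistent"],
            nat_counts=dict(d.get("nat_counts", {})),
            nat_candidate_counts=dict(d.get("nat_candidate_counts", {})),
            group_i_motif_counts=dict(d.get("group_i_motif_counts", {})),
            group_ii_exposed_counts=dict(d.get("group_ii_exposed_counts", {})),
            phospho=dict(d.get("phospho", {})),
            physchem=dict(d.get("physchem", {})),
            config=dict(d.get("config", {})),
        )


def summarize(
    evidence: Sequence[AcetylationEvidence],
    calls: Sequence[tuple[NmeStatus, Optional[NatAssignment]]],
) -> SummaryReport:
    """Aggregate per-record calls into a :class:`SummaryReport`.

    ``calls`` pairs each evidence record with its NME status and Nat
    assignment (the assignment may be None for INCONSISTENT records).
    Group (i) records contribute their iMet dipeptide motif (e.g.
    ``Met-Glu``); group (ii) records contribute their exposed residue.
    """
    if len(evidence) != len(calls):
        raise InputError(
            f"{len(evidence)} evidence records but {len(calls)} calls"
        )
    rep = SummaryReport(total=len(evidence))
    rep.nat_counts = {k: 0 for k in
                      ("NatA", "NatB", "NatCEF_ambiguous", "NatF", "unassigned")}
    rep.nat_candidate_counts = {k: 0 for k in ALL_NAT_TYPES}
    rep.nat_candidate_counts["ambiguous"] = 0
    rep.nat_candidate_counts["unassigned"] = 0
    rep.phospho = {
        "n_with_phospho": 0,
        "n_group_i_phospho": 0,
        "n_group_ii_phospho": 0,
        "n_acetyl_residue_also_phospho": 0,
    }
    for ev, (status, nat) in zip(evidence, calls):
        kind = status.status
        if kind is NmeStatusKind.INCONSISTENT:
            rep.n_inconsistent += 1
        elif kind is NmeStatusKind.NME_INDEPENDENT:
            rep.n_group_i += 1
            motif = f"{_aa3(ev.residues[0])}-{_aa3(ev.residues[1])}"
            rep.group_i_motif_counts[motif] = (
                rep.group_i_motif_counts.get(motif, 0) + 1
            )
        else:
            rep.n_group_ii += 1
            aa = _aa3(ev.residues[0])
            rep.group_ii_exposed_counts[aa] = (
                rep.group_ii_exposed_counts.get(aa, 0) + 1
            )
        if nat is not None and kind is not NmeStatusKind.INCONSISTENT:
            rep.nat_counts[RULE_COUNT_KEYS[nat.rule_id]] += 1
            if nat.unassigned:
                rep.nat_candidate_counts["unassigned"] += 1
            else:
                for cand in nat.candidates:
                    rep.nat_candidate_counts[cand] += 1
                if nat.ambiguous:
                    rep.nat_candidate_counts["ambiguous"] += 1
        if ev.phospho_positions:
            rep.phospho["n_with_phospho"] += 1
            if kind is NmeStatusKind.NME_INDEPENDENT:
                rep.phospho["n_group_i_phospho"] += 1
            elif kind is NmeStatusKind.NME_DEPENDENT:
                rep.phospho["n_group_ii_phospho"] += 1
            if 1 in ev.phospho_positions:
                rep.phospho["n_acetyl_residue_also_phospho"] += 1
    # deterministic ordering for serialization
    rep.group_i_motif_counts = dict(
        sorted(rep.group_i_motif_counts.items(),
               key=lambda kv: (-kv[1], kv[0]))
    )
    rep.group_ii_exposed_counts = dict(
        sorted(rep.group_ii_exposed_counts.items(),
               key=lambda kv: (-kv[1], kv[0]))
    )
    return rep


def attach_physchem_aggregates(rep: SummaryReport, rows: Sequence[dict]) -> None:
    """Fill ``rep.physchem`` from per-protein physicochemistry rows.

    Rows carry keys ``pI`` (float or None), ``enrichable`` and ``reason``.
    The median pI is taken over records with a defined pI.
    """
    pis = [r["pI"] for r in rows if r.get("pI") is not None]
    by_reason: dict[str, int] = {}
    for r in rows:
        if r.get("enrichable"):
            reason = r.get("reason") or "unspecified"
            by_reason[reason] = by_reason.get(reason, 0) + 1
    rep.physchem = {
        "median_pI": round(median(pis), 3) if pis else None,
        "n_pI_defined": len(pis),
        "n_enrichable": sum(by_reason.values()),
        "n_enrichable_by_reason": dict(sorted(by_reason.items())),
    }
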
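"""Synthetic proteomes and acetylation-evidence tables.

The generator emulates the structure of the study's evidence: every
protein is nuclear-encoded (starts with Met), its second residue is
drawn according to a Nat substrate class, the initiator Met is excised
exactly when the class is NME-dependent, and the observed evidence
peptide is the mature acetylated N-terminus.  A phosphosite may be
co-injected on an S/T/Y within the evidence window, and an optional
acidity-based filter emulates TiO₂ co-enrichment.

Default class weights are the empirical proportions of the study's
58-protein evidence table; the default phospho probability is its
observed 16/58 co-modification rate.

The pseudo-random stream is a single ``numpy`` generator with a fixed
draw order per protein — class, length, downstream residues, phospho —
so one seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .io import AcetylationEvidence, ProteinRecord, write_evidence_tsv, write_fasta
from .physchem import EnrichmentThresholds, IonizableModel, acidity_profile, tio2_enrichable
from .rules import (
    NmeStatusKind,
    ParsedNTerm,
    assign_nat,
    classify_from_nterm_only,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Second residues with no applicable Nat rule behind a retained Met.
_UNRULED_SECOND = "HKMQRWY"

#: class name → (second residue or None to draw, Met excised?, Nat set, rule id)
CLASS_TABLE: dict[str, tuple[Optional[str], bool, frozenset[str], Optional[str]]] = {
    "NatA_A": ("A", True, frozenset({"NatA"}), "R1"),
    "NatA_S": ("S", True, frozenset({"NatA"}), "R1"),
    "NatA_G": ("G", True, frozenset({"NatA"}), "R1"),
    "NatA_T": ("T", True, frozenset({"NatA"}), "R1"),
    "NatA_V": ("V", True, frozenset({"NatA"}), "R1"),
    "NatA_C": ("C", True, frozenset({"NatA"}), "R1"),
    "NatB_ME": ("E", False, frozenset({"NatB"}), "R2"),
    "NatB_MD": ("D", False, frozenset({"NatB"}), "R2"),
    "NatB_MN": ("N", False, frozenset({"NatB"}), "R2"),
    "NatCEF_ML": ("L", False, frozenset({"NatC", "NatE", "NatF"}), "R3"),
    "NatCEF_MI": ("I", False, frozenset({"NatC", "NatE", "NatF"}), "R3"),
    "NatCEF_MF": ("F", False, frozenset({"NatC", "NatE", "NatF"}), "R3"),
    "NatF_MG": ("G", False, frozenset({"NatF"}), "R4"),
    "unruled": (None, False, frozenset(), None),
}

#: Empirical class proportions of the study's 58-row evidence table.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "NatA_A": float(Fraction(25, 58)),
    "NatA_S": float(Fraction(13, 58)),
    "NatA_G": float(Fraction(7, 58)),
    "NatA_T": float(Fraction(1, 58)),
    "NatA_V": float(Fraction(1, 58)),
    "NatB_ME": float(Fraction(8, 58)),
    "NatB_MD": float(Fraction(1, 58)),
    "NatCEF_ML": float(Fraction(1, 58)),
    "NatF_MG": float(Fraction(1, 58)),
}


@dataclass
class SyntheticConfig:
    """Conditions for one synthetic dataset.

    ``class_weights`` maps generator classes (see :data:`CLASS_TABLE`) to
    probabilities summing to 1.  ``mean_length``/``length_sd`` set the
    normal length distribution of the precursors (clamped below at
    ``evidence_window`` + 2).  ``phospho_prob`` is the chance a peptide
    carries one phosphosite on an S/T/Y within the evidence window.
    """

    n_proteins: int = 58
    class_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    mean_length: float = 300.0
    length_sd: float = 80.0
    evidence_window: int = 14
    phospho_prob: float = float(Fraction(16, 58))
    apply_enrichment_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise InputError("n_proteins must be >= 1")
        unknown = set(self.class_weights) - set(CLASS_TABLE)
        if unknown:
            raise InputError(f"unknown generator class(es) {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"class weights sum to {total!r}, expected 1")
        if any(w < 0 for w in self.class_weights.values()):
            raise InputError("class weights must be non-negative")
        if not 0.0 <= self.phospho_prob <= 1.0:
            raise InputError("phospho_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruthRecord:
    """Ground truth for one generated protein."""

    protein_id: str
    class_name: str
    nme_status: NmeStatusKind
    nat_set: frozenset[str]
    rule_id: Optional[str]
    phospho_positions: tuple[int, ...]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[AcetylationEvidence], list[SyntheticTruthRecord]]:
    """Generate proteins, evidence and ground truth under ``config``.

    The truth is checked against the rule modules at generation time:
    classifying each emitted evidence record must reproduce the recorded
    class exactly (the rules are the generator's inverse).
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(config.class_weights)
    weights = np.array([config.class_weights[c] for c in names], dtype=float)
    weights = weights / weights.sum()

    min_len = config.evidence_window + 2
    proteins: list[ProteinRecord] = []
    evidence: list[AcetylationEvidence] = []
    truth: list[SyntheticTruthRecord] = []
    for i in range(config.n_proteins):
        # draw order: class, length, downstream residues, phospho
        cls = names[int(rng.choice(len(names), p=weights))]
        second, excised, nat_set, rule_id = CLASS_TABLE[cls]
        if second is None:
            second = _UNRULED_SECOND[int(rng.integers(len(_UNRULED_SECOND)))]
        length = max(min_len, int(round(rng.normal(config.mean_length,
                                                   config.length_sd))))
        tail = "".join(_AA[j] for j in rng.integers(0, len(_AA), length - 2))
        seq = "M" + second + tail
        protein = ProteinRecord(f"syn{i:05d}", seq, f"synthetic class {cls}")

        mature = seq[1:] if excised else seq
        window = mature[: config.evidence_window]
        phospho: tuple[int, ...] = ()
        if rng.random() < config.phospho_prob:
            sty = [k + 1 for k, aa in enumerate(window) if aa in "STY"]
            if sty:
                phospho = (sty[int(rng.integers(len(sty)))],)
        flags = tuple(p + 1 in phospho for p in range(len(window)))
        parsed = ParsedNTerm(tuple(window), True, flags)
        ev = AcetylationEvidence(
            protein_id=protein.id,
            nterm_label=parsed.render(),
            residues=list(window),
            acetylated=True,
            phospho_positions=sorted(phospho),
            nat_annotation=_nat_label(nat_set),
            description=protein.description,
        )
        rec = SyntheticTruthRecord(
            protein_id=protein.id,
            class_name=cls,
            nme_status=(NmeStatusKind.NME_DEPENDENT if excised
                        else NmeStatusKind.NME_INDEPENDENT),
            nat_set=nat_set,
            rule_id=rule_id,
            phospho_positions=phospho,
        )
        _self_check(parsed, rec)
        proteins.append(protein)
        evidence.append(ev)
        truth.append(rec)

    if config.apply_enrichment_filter:
        kept = apply_enrichment(evidence)
        kept_ids = {ev.protein_id for ev in kept}
        proteins = [p for p in proteins if p.id in kept_ids]
        truth = [t for t in truth if t.protein_id in kept_ids]
        evidence = kept
    return proteins, evidence, truth


def _nat_label(nat_set: frozenset[str]) -> str:
    if not nat_set:
        return "unassigned"
    return ", or ".join(sorted(nat_set))


def _self_check(parsed: ParsedNTerm, rec: SyntheticTruthRecord) -> None:
    status = classify_from_nterm_only(parsed)
    nat = assign_nat(parsed, status)
    if status.status is not rec.nme_status or nat.candidates != rec.nat_set:
        raise AssertionError(
            f"generator self-check failed for {rec.protein_id}: "
            f"classified {status.status}/{set(nat.candidates)} but truth is "
            f"{rec.nme_status}/{set(rec.nat_set)}"
        )


def apply_enrichment(
    evidence: Sequence[AcetylationEvidence],
    thresholds: Optional[EnrichmentThresholds] = None,
    model: Optional[IonizableModel] = None,
) -> list[AcetylationEvidence]:
    """Retain exactly the records a TiO₂ column would capture.

    Each acetyl-peptide is profiled with a blocked α-amino group and its
    phosphosites included, then kept iff :func:`tio2_enrichable` is true.
    """
    thresholds = thresholds or EnrichmentThresholds()
    model = (model or IonizableModel()).acetylated()
    kept = []
    for ev in evidence:
        profile = acidity_profile(ev.residues,
                                  n_phospho=len(ev.phospho_positions),
                                  model=model)
        ok, _ = tio2_enrichable(ev, profile, thresholds)
        if ok:
            kept.append(ev)
    return kept


def write_truth_tsv(truth: Sequence[SyntheticTruthRecord],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tclass\tnme_status\tnat_set\trule_id\t"
                 "phospho_positions\n")
        for t in truth:
            fh.write(
                f"{t.protein_id}\t{t.class_name}\t{t.nme_status.value}\t"
                f"{','.join(sorted(t.nat_set))}\t{t.rule_id or ''}\t"
                f"{','.join(str(p) for p in t.phospho_positions)}\n"
            )


def write_dataset(proteins: Sequence[ProteinRecord],
                  evidence: Sequence[AcetylationEvidence],
                  truth: Sequence[SyntheticTruthRecord],
                  out_dir: str | Path) -> dict[str, Path]:
    """Emit FASTA + evidence TSV + truth TSV into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "evidence": out / "evidence.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(proteins, paths["fasta"])
    write_evidence_tsv(evidence, paths["evidence"])
    write_truth_tsv(truth, paths["truth"])
    return paths
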
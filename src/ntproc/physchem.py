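"""Peptide physicochemistry: net charge, isoelectric point, acidity.

TiO₂ affinity columns are designed to capture phosphopeptides, but
highly acidic peptides — low isoelectric point (pI) or several Asp/Glu
residues — co-adsorb.  This module provides the Henderson–Hasselbalch
charge model behind that analysis: each ionizable group contributes a
fractional charge at a given pH,

    basic groups:   +1 / (1 + 10^(pH − pKa))
    acidic groups:  −1 / (1 + 10^(pKa − pH))

and the pI is the unique pH in [0, 14] where the (strictly
non-increasing) net charge crosses zero, located by bisection.

An Nα-acetylated N-terminus has no free α-amino group, so acetylation
removes that ionization entirely; a phosphosite contributes a pair of
acidic ionizations (default pKa 1.2 and 6.5).  The side-chain and
terminal pKa values default to the Bjellqvist-style table popularized by
ProtParam (and shipped by Biopython), and are editable via config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InputError, UndefinedValueError, ValidationError
from .io import STANDARD_AA, AcetylationEvidence

#: Bjellqvist-style pKa values (as used by ProtParam / Bio.SeqUtils).
DEFAULT_SIDE_CHAIN_PKA = {
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,   # acidic side chains
    "H": 5.98, "K": 10.0, "R": 12.0,             # basic side chains
}
DEFAULT_N_TERM_PKA = 7.5
DEFAULT_C_TERM_PKA = 3.55
DEFAULT_PHOSPHO_PKA = (1.2, 6.5)

ACIDIC_SIDE_CHAINS = frozenset("DECY")
BASIC_SIDE_CHAINS = frozenset("HKR")


@dataclass(frozen=True)
class IonizableModel:
    """The ionizable groups of a peptide and their pKa values.

    ``n_term_blocked`` models Nα-acetylation (no free α-amino group);
    ``c_term_blocked`` models C-terminal amidation.
    """

    side_chain_pka: dict = field(default_factory=lambda: dict(DEFAULT_SIDE_CHAIN_PKA))
    n_term_pka: float = DEFAULT_N_TERM_PKA
    c_term_pka: float = DEFAULT_C_TERM_PKA
    phospho_pka: tuple[float, float] = DEFAULT_PHOSPHO_PKA
    n_term_blocked: bool = False
    c_term_blocked: bool = False

    def __post_init__(self) -> None:
        for name, val in {**self.side_chain_pka,
                          "n_term": self.n_term_pka,
                          "c_term": self.c_term_pka}.items():
            if not 0.0 < val < 14.0:
                raise InputError(f"pKa for {name} must lie in (0, 14), got {val}")
        if not self.phospho_pka[0] < self.phospho_pka[1]:
            raise InputError("phospho first ionization must precede the second")

    def acetylated(self) -> "IonizableModel":
        """Copy of this model with the α-amino group blocked."""
        return replace(self, n_term_blocked=True)


def _ionizations(peptide: Sequence[str], model: IonizableModel,
                 n_phospho: int) -> tuple[list[float], list[float]]:
    """(acidic pKas, basic pKas) for a peptide under a model."""
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValidationError(f"illegal residue(s) {sorted(bad)}")
    acidic: list[float] = []
    basic: list[float] = []
    for aa in peptide:
        pka = model.side_chain_pka.get(aa)
        if pka is None:
            continue
        (acidic if aa in ACIDIC_SIDE_CHAINS else basic).append(pka)
    if not model.n_term_blocked:
        basic.append(model.n_term_pka)
    if not model.c_term_blocked:
        acidic.append(model.c_term_pka)
    for _ in range(n_phospho):
        acidic.extend(model.phospho_pka)
    return acidic, basic


def net_charge(peptide: Sequence[str],
               pH: Union[float, np.ndarray],
               model: Optional[IonizableModel] = None,
               n_phospho: int = 0) -> Union[float, np.ndarray]:
    """Net charge of a peptide at a pH (scalar or array), in unit charges."""
    model = model or IonizableModel()
    acidic, basic = _ionizations(peptide, model, n_phospho)
    pH = np.asarray(pH, dtype=float)
    charge = np.zeros_like(pH)
    for pka in basic:
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka))
    for pka in acidic:
        charge -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return float(charge) if charge.ndim == 0 else charge


def isoelectric_point(peptide: Sequence[str],
                      model: Optional[IonizableModel] = None,
                      n_phospho: int = 0,
                      tol: float = 1e-3) -> float:
    """pI: the pH in [0, 14] where the net charge is zero, by bisection.

    The net charge is strictly non-increasing in pH, so the zero is
    unique when it exists.  Raises :class:`UndefinedValueError` when the
    charge does not change sign on [0, 14] (e.g. a peptide with no basic
    group, or none ionizable at all).
    """
    model = model or IonizableModel()
    lo, hi = 0.0, 14.0
    c_lo = net_charge(peptide, lo, model, n_phospho)
    c_hi = net_charge(peptide, hi, model, n_phospho)
    if c_lo < 0.0 or c_hi > 0.0 or (c_lo == 0.0 and c_hi == 0.0):
        raise UndefinedValueError(
            "net charge does not cross zero on [0, 14]; pI undefined"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(peptide, mid, model, n_phospho) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PeptidePhyschem:
    """Acidity profile of one observed peptide.

    ``pI`` is None when the charge never crosses zero on [0, 14]; in that
    case ``charge_sign`` records whether the peptide is permanently
    negative (−1, purely acidic) or permanently positive (+1).
    """

    pI: Optional[float]
    acidic_count: int
    acidic_fraction: float
    n_phospho: int
    charge_sign: int = 0


def acidity_profile(peptide: Sequence[str],
                    n_phospho: int = 0,
                    model: Optional[IonizableModel] = None) -> PeptidePhyschem:
    """Acidic-residue content and pI of an observed peptide.

    ``acidic_count`` counts Asp + Glu only (the acidity criterion of the
    enrichment analysis); phospho groups enter the pI through their two
    ionizations but not the acidic-residue count.
    """
    model = model or IonizableModel()
    n_acidic = sum(1 for aa in peptide if aa in "DE")
    try:
        pi: Optional[float] = isoelectric_point(peptide, model, n_phospho)
        sign = 0
    except UndefinedValueError:
        pi = None
        mid = net_charge(peptide, 7.0, model, n_phospho)
        sign = -1 if mid < 0 else 1
    return PeptidePhyschem(
        pI=pi,
        acidic_count=n_acidic,
        acidic_fraction=n_acidic / len(peptide) if peptide else 0.0,
        n_phospho=n_phospho,
        charge_sign=sign,
    )


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Decision thresholds for TiO₂ co-enrichment.

    ``pi_max``: a peptide at or below this pI counts as highly acidic.
    ``min_acidic``: at least this many Asp+Glu counts as multiply acidic.
    """

    pi_max: float = 4.5
    min_acidic: int = 3


def tio2_enrichable(evidence: AcetylationEvidence,
                    profile: PeptidePhyschem,
                    config: Optional[EnrichmentThresholds] = None
                    ) -> tuple[bool, Optional[str]]:
    """Would this acetyl-peptide be retained on a TiO₂ column?

    Criteria, in order: any phosphosite ("phospho"); pI at or below
    ``pi_max`` ("low_pI" — a peptide whose charge is negative over the
    whole pH range is more acidic than any finite pI and also qualifies);
    at least ``min_acidic`` Asp+Glu residues ("multi_acidic").
    """
    config = config or EnrichmentThresholds()
    if evidence.phospho_positions or profile.n_phospho > 0:
        return True, "phospho"
    low_pi = (profile.pI is not None and profile.pI <= config.pi_max) or \
             (profile.pI is None and profile.charge_sign < 0)
    if low_pi:
        return True, "low_pI"
    if profile.acidic_count >= config.min_acidic:
        return True, "multi_acidic"
    return False, None
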
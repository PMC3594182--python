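"""Position-frequency matrices, logo information content, and the
acetyl-CoA binding-motif scanner.

Acetylated N-termini are aligned at the acetylated residue (index 1) and
the fourteen positions downstream are tallied into a position frequency
matrix (PFM), the numerical backbone of a sequence logo.  Column heights
follow the Schneider–Stephens definition: IC = log2(20) − H(column), with
an optional small-sample correction of (s − 1)/(2·ln2·n) bits for s = 20
residue states.

Catalytic subunits of the N-acyltransferase superfamily carry the
conserved acetyl-CoA binding motif R-x-x-G-x-[G/A]; :func:`scan_accoa_motif`
reports every (possibly overlapping) 6-residue window matching it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError, UndefinedValueError, ValidationError
from .io import STANDARD_AA, ProteinRecord

AA_ORDER = tuple(sorted(STANDARD_AA))

LOG2_20 = math.log2(20)

#: Overlap-tolerant AcCoA motif pattern (R..G.[GA]) via lookahead capture.
_ACCOA_RE = re.compile(r"(?=(R[ACDEFGHIKLMNPQRSTVWY]{2}G[ACDEFGHIKLMNPQRSTVWY][GA]))")


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue counts over aligned N-terminal windows.

    ``counts[i]`` maps residue → count at alignment position i+1;
    ``pad_counts[i]`` counts the windows too short to cover that
    position.  At every position, residue counts + pads = ``n_sequences``.
    """

    length: int
    counts: list[dict[str, int]]
    pad_counts: list[int]
    n_sequences: int

    def coverage(self, position: int) -> int:
        """Number of windows covering a 1-based position."""
        return self.n_sequences - self.pad_counts[position - 1]

    def frequencies(self, position: int) -> dict[str, float]:
        """Residue frequencies at a 1-based position (pads excluded)."""
        n = self.coverage(position)
        if n == 0:
            raise UndefinedValueError(f"position {position} is fully padded")
        return {aa: c / n for aa, c in self.counts[position - 1].items()}

    def to_tsv(self, path: str | Path) -> None:
        """Export as positions × residues count table for logo renderers."""
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(AA_ORDER) + "\tpad\n")
            for i in range(self.length):
                row = [str(self.counts[i].get(aa, 0)) for aa in AA_ORDER]
                fh.write(f"{i + 1}\t" + "\t".join(row) +
                         f"\t{self.pad_counts[i]}\n")


def build_pfm(windows: Iterable[Sequence[str]],
              length: int = 14) -> PositionFrequencyMatrix:
    """Tally aligned residue windows into a PFM.

    Windows are aligned so index 1 is the acetylated residue.  Windows
    shorter than ``length`` increment ``pad_counts`` beyond their end;
    residues beyond ``length`` are ignored.  The ambiguity code X is
    tolerated and tallied as padding (excluded from statistics).
    """
    if length < 1:
        raise InputError("PFM length must be >= 1")
    counts: list[dict[str, int]] = [dict() for _ in range(length)]
    pads = [0] * length
    n = 0
    for window in windows:
        n += 1
        for i in range(length):
            if i < len(window):
                aa = window[i]
                if aa == "X":
                    pads[i] += 1
                    continue
                if aa not in STANDARD_AA:
                    raise ValidationError(f"illegal residue {aa!r} in window")
                counts[i][aa] = counts[i].get(aa, 0) + 1
            else:
                pads[i] += 1
    return PositionFrequencyMatrix(length, counts, pads, n)


def column_information(pfm: PositionFrequencyMatrix, position: int,
                       small_sample_correction: bool = False) -> float:
    """Information content of a logo column, in bits.

    IC = log2(20) − H where H is the Shannon entropy of the column's
    residue frequencies.  With ``small_sample_correction`` the
    approximation error term e(n) = 19/(2·ln2·n) is subtracted before
    clamping to [0, log2(20)].
    """
    n = pfm.coverage(position)
    if n == 0:
        raise UndefinedValueError(f"position {position} is fully padded")
    freqs = pfm.frequencies(position)
    h = -sum(f * math.log2(f) for f in freqs.values() if f > 0.0)
    ic = LOG2_20 - h
    if small_sample_correction:
        ic -= (len(STANDARD_AA) - 1) / (2.0 * math.log(2) * n)
    return min(max(ic, 0.0), LOG2_20)


@dataclass(frozen=True)
class MotifHit:
    """One AcCoA binding-motif match."""

    sequence_id: str
    start: int  # 1-based
    matched_text: str


def scan_accoa_motif(protein: ProteinRecord) -> list[MotifHit]:
    """Find every R-x-x-G-x-[G/A] window (overlaps included, 1-based starts)."""
    return [
        MotifHit(protein.id, m.start() + 1, m.group(1))
        for m in _ACCOA_RE.finditer(protein.sequence)
    ]


def write_motif_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tmatch\n")
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.matched_text}\n")
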
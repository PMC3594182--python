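# Methods

## The processing model

`ntproc` annotates the two co-translational events that shape the mature
N-terminus of a nuclear-encoded eukaryotic protein:

1. **N-terminal Met excision (NME).** Methionine aminopeptidases remove
   the initiator Met (iMet) when the second residue has a small side
   chain. The rule implemented is exactly: excision iff position 2 ∈
   {Ala, Val, Ser, Thr, Cys, Gly, Pro} (`predict_nme`).
2. **Nα-acetylation.** One of the N-terminal acetyltransferases
   (NatA–NatF) transfers an acetyl group from acetyl-CoA to the free
   α-amino group. Substrate specificity is encoded as an ordered rule
   table over the observed acetylated N-terminus (`assign_nat`):

   | rule | condition | candidates |
   |------|-----------|------------|
   | R1 | Met excised, exposed residue ∈ {S,A,T,V,G,C} | NatA |
   | R2 | Met retained, residue 2 ∈ {D,E,N} | NatB |
   | R3 | Met retained, residue 2 ∈ {L,I,F} | NatC, NatE, NatF |
   | R4 | Met retained, residue 2 ∈ {S,A,T,V,G,C} | NatF |
   | R5 | otherwise | unassigned |

   The NME status gates the two regimes, so at most one rule fires and
   the assignment is a pure function of its inputs. Ambiguous sets (R3)
   are reported as sets and never collapsed to one enzyme; headline
   counts tally by rule, so R3 rows do not inflate the NatA/NatB totals.
   Deliberate gaps: NatD is never emitted (its histone substrates are
   outside the evidence this pipeline handles), and an exposed Pro after
   excision is classifiable as NME-dependent but receives no Nat (Pro
   licenses excision but is not a recorded acetylation substrate).
   Met-Cys falls under R4, since Cys is among the small residues NatF
   can acetylate behind a retained Met.

An observed acetylated N-terminus is classified **group (i)**
(NME-independent: acetylated residue is the retained iMet) or
**group (ii)** (NME-dependent: acetylated residue is the one exposed at
precursor position 2). With precursor sequences available (*sequence
mode*) the observed peptide is anchored against the precursor and
mismatches are flagged INCONSISTENT; without them (*nterm-only mode*,
the default for the packaged evidence table) a canonical Met start is
assumed, so an acetylated non-Met first residue implies excision. The
assumption is safe for the packaged data — every protein in it is
nuclear-encoded — but nterm-only mode cannot detect internal peptides
misreported as N-termini.

## Logo statistics

Evidence peptides are aligned at the acetylated residue (position 1) and
tallied over a 14-position window into a position frequency matrix.
Peptides shorter than the window contribute padding, and padded slots
are excluded from the frequency denominator rather than imputed, so
column frequencies always sum to 1 over the covering sequences. Column
information content follows Schneider–Stephens:
IC = log₂20 − H(column), clamped to [0, log₂20], with an optional
small-sample correction term e(n) = 19/(2·ln2·n) bits (default **off**;
both modes are exposed because published logos rarely state which was
used). PFMs export as plain TSV for external logo renderers; no
graphics are produced here.

The acetyl-CoA binding motif of N-acyltransferase catalytic subunits is
scanned as the strict 6-position pattern R-x-x-G-x-[G/A], x being any of
the 20 standard residues; overlapping windows are all reported.

## Peptide physicochemistry

Net charge uses the Henderson–Hasselbalch fractional-charge model:
+1/(1+10^(pH−pKa)) per basic group, −1/(1+10^(pKa−pH)) per acidic group.
The pKa table defaults to the Bjellqvist-style values popularized by
ProtParam (side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0,
R 12.0; α-amino 7.5; α-carboxyl 3.55) and ships as editable config so,
e.g., EMBOSS values can be swapped in. Nα-acetylation removes the
α-amino ionization entirely; a phosphosite adds two acidic ionizations
(default pKa 1.2 and 6.5, configurable).

Net charge is strictly non-increasing in pH, so the isoelectric point
is the unique zero crossing on [0, 14], found by bisection to 0.001 pH.
Short acetylated peptides often have **no basic group at all**; their
charge is negative over the whole range and the pI is undefined. Such
peptides are recorded with pI = null and counted as "low pI" for
enrichment purposes (they are more acidic than any finite pI); report
medians are taken over defined pI values only.

TiO₂ co-enrichment is decided per peptide in fixed order: any
phosphosite → enrichable ("phospho"); else pI ≤ `pi_max` → enrichable
("low_pI"); else ≥ `min_acidic` Asp+Glu residues → enrichable
("multi_acidic"); else not enrichable. Defaults `pi_max = 4.5` and
`min_acidic = 3` make "highly acidic" concrete; both are config keys and
are echoed into every report. No acetyl-moiety–TiO₂ interaction term is
modeled, and no retention or binding-energy chemistry is attempted.
Because a peptide with three acidic residues usually also has a low pI,
the "multi_acidic" reason mostly appears for acid-rich peptides whose
basic residues keep the pI above threshold.

## Synthetic data

The generator emulates the structure of the packaged evidence: each
protein starts with Met, its second residue is drawn from a Nat
substrate class, the Met is excised exactly when the class is
NME-dependent, and the emitted evidence peptide is the first 14 residues
of the mature N-terminus. Default class weights are the empirical
proportions of the 58-row evidence table (Ala 25/58, Ser 13/58, Gly
7/58, Thr 1/58, Val 1/58 for exposed NatA substrates; Met-Glu 8/58,
Met-Asp 1/58 for NatB; Met-Leu 1/58 for NatC/E/F; Met-Gly 1/58 for
NatF), the default phospho co-modification probability is the observed
16/58, and precursor lengths are Normal(300, 80) truncated below —
typical cytosolic protein lengths. One `numpy` generator with a fixed
per-protein draw order (class, length, downstream residues, phospho)
makes a seed reproduce the dataset byte for byte. The `NatF_MG` class
retains its Met by construction, mirroring the documented exception
where a Met-Gly- terminus escapes excision and is acetylated intact.

The generator self-checks at emission time: the rule engine must
reproduce each record's class, so the rules are the generator's exact
inverse. Passing recovery tests therefore demonstrates internal
consistency and correct bookkeeping, not biological realism: downstream
residues are uniform (no compositional bias), peptide lengths are fixed
at the window, there is no identification noise, no missed cleavage, no
paralog sharing of peptides, and at most one phosphosite per peptide.

## Problem sizes in the test suite

Unit and property tests run on the packaged 58-row table and on
synthetic datasets of 10–300 proteins; parameter-recovery checks use
n = 2000 with a 3-binomial-SE band; the pI bisection is validated
against an exhaustive 10⁻⁴ pH-grid oracle on 500 random peptides and
against Biopython's independent implementation on 50; the motif scanner
against a brute-force window oracle on 1000 random sequences. The whole
suite completes in well under a minute.

## Known limitations

- Nat assignment reflects yeast/human substrate spectra; it is a
  sequence rule, not a claim that the orthologous enzyme was observed.
- nterm-only mode cannot produce INCONSISTENT calls; validation against
  precursors requires FASTA input.
- Peptide-level deduplication (several paralogous proteins sharing one
  observed peptide) is out of scope; counts are per protein.
- The enrichment thresholds are operational definitions, not measured
  binding properties of TiO₂.
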
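# Methods

## Profile model

A PRM's binding preference is modeled as a gap-free alignment of its selected
peptides summarized by a weighted PWM. For column *j* with residue
frequencies `f_ij` (pads at row ends excluded from the column depth), the
weight is `W_ij = f_ij · (max_i f_ij − min_i f_ij)` and the specificity
potential is `SP_j = Σ_i W_ij`, which reduces algebraically to
`max_i f_ij − min_i f_ij`. The minimum is taken over the **full alphabet**,
so any absent residue pins it at 0. This is the only reading under which a
column uniform over the alphabet scores exactly 0 and a fully conserved
column exactly 1, and it makes SP equal the modal frequency in typical data.
No pseudo-counts are applied: the weights are meant to be pure observed
frequencies, and smoothing would destroy the SP = 0/1 anchor points.

The alphabet defaults to 19 letters (no Cys) because the phage library
excludes cysteine; natural-sequence analyses use all 20 (configurable).

## Clustering and alignment

Peptides are grouped on shared ungapped k-mer seeds (k = 3 by default — the
shortest meaningful motif unit) and aligned by anchoring the seed. Groups are
merged at the relative offset maximizing a depth²-weighted sum of column
frequency ranges. A plain sum of ranges — the more obvious objective — turns
out to *prefer placing groups side by side*, because every column covered by
a single row already has range 1; squaring the column depth rewards stacking
rows so that conserved columns coincide, which is the intended behavior. Tie
offsets resolve to the smallest absolute shift, then the leftmost.

A peptide is an outlier when it shares no seed with at least
`ceil(10% · n)` other peptides; outliers are excluded from the alignment but
retained with a reason. When no peptides share any seed, the first peptide
is kept (with a warning) so downstream code still receives an alignment.
Curated alignments can be supplied verbatim via an override mapping
(sequence → start column), replacing the heuristic entirely; there are no
silent manual-curation steps.

Duplicate sequences are collapsed to one record before profile building
(unique peptides are the unit of analysis) while the raw record count stays
on the peptide set. The minimum input is two peptides — identical sequences
still align trivially when duplicates are kept deliberately.

## Glycine flanking, trimming, scores

The randomized 16-mer insert of the phage construct is flanked by invariant
glycines that can take part in recognition. When the extreme N- or
C-terminal column is specific (SP ≥ 0.33), an all-G column is appended at
that terminus and the PWM recomputed; rows whose peptide does not reach that
terminus receive a pad instead of a G, preserving the rows' gap-free
structure (the observed column is still pure glycine). The rule fires once
per terminus.

Terminal positions with SP < 0.2 are then trimmed iteratively; SPt sums SP
over retained positions with SP ≥ 0.2 (weak interior positions stay visible
in the logo but do not count). SPt is computed after glycine flanking, since
logos display the flank. Positions are classified specific at SP ≥ 0.33 —
the inclusive convention is used where sources disagree on strict vs
non-strict. Profiles pass the reliability gate with n ≥ 5 aligned peptides
and SPt > 1 (strict).

Note a structural caveat: in an offset alignment, extreme terminal columns
covered by one or two rows have SP near 1 by construction (depth-normalized
frequencies), so they survive trimming and inflate SPt. The planted-recovery
tests therefore locate planted positions through ground-truth offsets rather
than trusting profile boundaries.

## Hydropathy and composition

Roseman's water/octanol side-chain hydropathy scale, corrected for flanking
peptide-bond solvation, ships as a constants table (transcribed from the
Roseman 1988 scale as tabulated in AAindex entry ROSM880102; Gly = 0 by
definition). The hydropathy of a position is the frequency-weighted mean
RHI; of a sequence fragment, the unweighted mean over residues. Disorderome
fragmentation defaults to non-overlapping hexadecapeptides (window = step =
16, remainder dropped), with the step configurable. Category means over
positions are unweighted (each position counts once); SLiM statistics are
first averaged within a motif class and then across classes with equal
weight, so heavily annotated classes do not dominate. For SLiM categories
the distribution entries are the class-level means.

## Structure comparison

Chains with 5–30 polymer residues are ligand candidates; a longer chain is
PRM-like when its local-alignment identity to the query PRM exceeds 10% (the
floor below which no representative structure is accepted). Modified
residues map to their parent one-letter code for sequence extraction, are
flagged as PTM positions, and are excluded from similarity arithmetic.
Contacts are residue pairs whose closest side-chain atoms lie within 5 Å
(inclusive); glycine and residues with missing side-chain density use the
Cα as surrogate, since excluding them would silently drop real interface
residues. Altlocs resolve to the highest-occupancy conformer.

Peptides are compared by sliding one along the other without gaps; the
register maximizing group-based percent similarity wins (ties: smallest
absolute offset, then leftmost). With a specificity profile available, the
comparison span is the region aligned with the logo; without one, the span
is the structure-peptide residues in contact with the PRM. The best-matched
complex is the candidate with the highest ligand similarity, ties broken by
interface identity, then full identity, then PDB id — "high PRM identity"
is operationalized as this tie-break chain since no numeric rule beyond the
10% floor exists. Homology searching itself (e.g. PSI-BLAST against the PDB)
is out of scope: the candidate list arrives as input, keeping the pipeline
offline.

## Proteome scanning

The scan score of a window is the sum of the profile weights of its
residues, normalized by the profile's maximum attainable score; the
column-wise consensus scores exactly 1. The default reporting threshold of
0.7 keeps windows dominated by the conserved positions and is exposed as a
flag; a C-terminal anchoring option restricts matching to sequence ends for
termini-binding families (off by default). Standard residues absent from a
19-letter profile alphabet (Cys) score zero; windows containing non-standard
letters are skipped. This scoring scheme is this package's own design — it
is deliberately simple and carries no background-model significance.

## Synthetic data

The generators define the study conditions for all tests. Defaults: 50
hexadecapeptides per PRM over the 19-letter no-Cys alphabet; a planted
six-position motif (modal probabilities 0.80–0.90 at five specific
positions, one indifferent position) placed at an offset jittered ±3 around
the center; 5% of peptides drawn entirely from a uniform background as
outliers. Disordered regions are i.i.d. draws from a hydrophilic
composition with Trp pinned at 0.4% and disorder-promoting residues
(P, E, S, K, G, Q) dominant; its mean fragment RHI of about −0.86 emerges
from the composition rather than being set. Toy complexes place residues on
two rails 16 Å apart with planted contact side chains at 4.2–4.7 Å (±0.05 Å
per-axis jitter) and everything else beyond 6 Å, with a glycine planted
among the contact residues to exercise the Cα-surrogate rule.

One global seed drives independent per-generator substreams
(`SeedSequence(seed, spawn_key=(stream,))`), so adding a generator never
perturbs existing fixtures. Outliers are background draws rather than
shuffled real peptides, making outlier detection unambiguous.

What the synthetic data does *not* emulate: round-to-round phage-selection
enrichment, ELISA signal structure, sequence correlations within natural
disordered regions, multi-register (bidirectional) binding, and real
side-chain geometry (one pseudo-atom per side chain). Passing tests
therefore demonstrate correctness of the formulas, alignment, contact
mapping and scanning on data with the assumed statistical structure — not
robustness to the full messiness of experimental selections.

## Problem sizes and numerics

Tests and the acceptance script run at deliberately small scale: 1,000
random columns for the SP identity (tolerance 1e-12, an algebraic identity),
50-peptide recovery experiments, 5 toy complexes, 50 register alignments and
20 scanned 60-mers per run, and a few hundred disordered regions (~30k
residues) for composition checks — enough for every statistic tested while
keeping the whole suite in seconds. Frequency-convergence checks use 3σ
binomial bands and skip planted frequencies below 0.05, whose rare-count
tails are Poisson rather than normal. Scan scores accumulate per-column
contributions in a fixed order so the consensus window's relative score is
exactly 1.0 in floating point.

## Known limitations

* Low-depth terminal columns score SP ≈ 1 (see above); interpreting profile
  boundaries requires the peptide count per column, which the alignment
  retains.
* The k-mer outlier rule removes genuine motif carriers whose core deviates
  from the consensus at two or more seed positions (~20–30% at the default
  planted probabilities); the surviving alignment is slightly biased toward
  the consensus, which inflates per-column modal frequencies relative to the
  planted model.
* A random background peptide occasionally contains a motif-like k-mer and
  escapes the outlier rule; at the default conditions this occurs in well
  under 1% of peptides.
* The scan threshold is a ranking device, not a significance level.
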
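# Methods

## Coordinates and sequence handling

All residue numbering is 1-based and inclusive, matching the superscript
convention of the protein-chemistry literature (Thr214 is
`residue_at(record, 214)`); peptides carry their parent coordinates as
`start`–`end` inclusive ranges. Sequences are validated against the 20
standard one-letter codes; ambiguity codes are rejected unless explicitly
passed through. Lowercase input is uppercased silently and a terminal `*`
stop character is stripped with a warning. Alignments are read from aligned
FASTA or Clustal (conservation lines ignored); this package consumes
precomputed multiple alignments and never builds them.

## Mass model

Peptide masses are monoisotopic: the sum of residue masses (Unimod/standard
values, e.g. G 57.02146, E 129.04259) plus water (18.010565 Da), plus one
proton (1.007276 Da) for the MH⁺ ion observed in positive-mode MALDI.
Charge states beyond +1, average masses, and isotope envelopes are out of
scope — reflector MALDI of tryptic digests is effectively a singly
protonated, monoisotopic measurement.

Two modifications are modelled:

| modification | delta (Da) | targets | multiplicity |
|---|---|---|---|
| phospho | +79.96633 | S, T, Y | ≤ 1 per site |
| glycyl | +57.02146 per glycine | E | unbounded chain |

Variant enumeration combines every phospho-site subset with every polyglycine
chain length in a configured range (default 0–30). By default the chain
occupies at most one glutamate per peptide — single-site polyglycylation is
what is observed for these proteins — with an option for multi-site chains.
Variants are deduplicated by (site, multiplicity) content, so a zero-length
chain contributes exactly one unmodified variant.

Printed literature masses are matched at ±0.1 Da. Published peak labels
round inconsistently (values printed at one decimal can sit up to ~0.1 Da
from the full-precision computation), and one printed "MH⁺" value for the
19-mer DNLNLWVTDSAGDDNAEEK (2104.92) actually equals the neutral
monoisotopic mass (MH⁺ computes to 2105.93). The package therefore reports
both neutral mass and MH⁺ and never guesses which a label intended.

## Digestion

Cleavage is C-terminal to K/R except before proline ("trypsin strict").
The rule is consistent with every reported peptide (e.g. 202–219 retains
one internal K before L; 249–260 ends at the protein C-terminus).
Defaults: up to 2 missed cleavages, no length filter. The protein
N-terminal Met is not removed, since published residue numbering includes
it. Two structural properties are enforced by test: the zero-missed peptide
set tiles the parent exactly, and every k-missed peptide is a concatenation
of 1..k+1 consecutive zero-missed peptides.

## Peak lists and matching

Peak lists are centroided (m/z, intensity) pairs; construction sorts,
merges duplicates within 1e-6 Da, and checks the 750–4000 Da acquisition
window typical of reflector peptide fingerprinting. Matching uses an
absolute tolerance, default ±0.1 Da — the precision at which the reference
peak masses are reported. Intensity is ignored for matching and calling
(assignments of this kind rest on presence/absence); an optional
minimum-intensity filter exists but is off by default.

Phospho detection reports a positive call when both the unmodified and the
+79.96633 Da peak are present, or when the shifted peak alone is present
(the "exclusively phosphorylated" case, flagged as such).

### Ladder calling

A polyglycylation ladder is a peak series at `base MH⁺ + n × 57.02146`.
The caller is anchored at the unmodified MH⁺ *even when that rung is
absent*: a fully modified peptide shows no n = 0 peak, and the rung set may
start above zero. Extension proceeds upward from the smallest observed
rung, tolerating up to `max_gap` (default 1) consecutive missing rungs;
missing multiplicities below `k_max` are reported as gaps. A call requires
at least `min_rungs` = 3 observed rungs, because two coincidental tryptic
peaks 57 Da apart are common (glycine is a residue mass). The search is
bounded at `n_max` = 30 glycines, comfortably above the longest observed
chain (24).

## Signature motif

The pattern `[T/G] X{0,1} [D/E] X{1,3} G [D/E] X{1,2} E{2,4}` is matched
with full backtracking over element lengths. "Polar or negatively charged"
X is interpreted as {S, T, N, Q, C, Y} ∪ {D, E}; the set is configurable
because no exhaustive definition accompanies the pattern. Summing the
element bounds gives a minimal match length of 8 and maximal of 14. At each
start position the canonical match is chosen by (1) fewest class
violations, (2) longest total span, (3) earlier elements as long as
possible; overlapping matches at different starts are all reported, and
the terminal glutamate run is returned as the candidate glycylation sites.
A bounded fuzzy mode (`strictness=k`) admits up to k residue-level
violations and records them, because the pattern as printed does not
strictly match every experimentally verified glycylation context (the
g14-3-3 Glu246 context itself contains alanines at X positions under any
plausible X set). The scanner is verified against an independent
exhaustive-enumeration oracle over all element-length combinations.

## Conservation statistics

Pairwise statistics come from an optimal global (end-to-end) alignment
under affine gaps (a gap of length L costs `open + (L−1) × extend`),
computed by Bio.Align.PairwiseAligner and cross-checked in the tests
against an independent 3-state dynamic-programming oracle. Presets:
BLOSUM62 with open 10 / extend 0.5 (default), and GONNET1992 with open 10 /
extend 0.2 approximating classic ClustalW pairwise parameters — provided
because published percent-identity figures depend on the aligner
generation used. Identity is identical columns over the full alignment
length; similarity additionally counts substitutions with a positive
matrix score; a "shorter-sequence" denominator is available as a switch.
Reproducing printed identity/similarity percentages for the full-length
proteins requires the full database sequences and the original aligner
parameters, and is deliberately not asserted by the test suite; the
statistics conventions themselves are exercised on short sequences where
the optimum is provable.

Multiple-alignment columns are classified `invariant` (all rows identical,
no gap), `conserved_k` (some residue in ≥ k rows, default k = 2), or
`divergent` — the three shading classes of family alignment figures.
`map_position` carries 1-based positions across an alignment (returning a
gap marker where unresolvable) so reference annotations such as bridge
positions can be projected onto homologs.

## Dimer compatibility

Classification is purely residue-identity based: a bridge position pair is
`intact` when one residue is basic {K, R} and the other acidic {D, E},
`repulsive` when both fall in the same charged set, `neutral` otherwise.
Histidine is excluded from the basic set by default (mostly uncharged at
physiological pH); both sets are parameters. The compatibility score is
intact − repulsive, and partners are ranked by score, then intact count,
then id. No geometry, docking or energetics is modelled — this is exactly
the level at which interface conservation arguments are made from sequence
alone. The packaged table `data/bridges.tsv` lists the residue pairs at the
homologous bridge positions of human 14-3-3ζ, Drosophila LeoII and
D14-3-3ε, and Giardia g14-3-3, for the four homodimers and the two
Giardia/Drosophila heterodimers.

## Synthetic data

Generators are fully deterministic under a single integer seed (one
`numpy` generator per call) and always emit ground truth alongside the
data; downstream tests consume (data, truth) pairs only.

*Proteins*: background residues are drawn from an alphabet containing no
T/G/D/E and no default-X members, so the background cannot form any part of
the signature pattern and the only matches are the planted ones; planted
instances sample element lengths uniformly within bounds, with X positions
drawn from the polar-uncharged subset so a planted instance cannot seed a
second overlapping match.

*Spectra*: one peak per declared variant at MH⁺ plus Gaussian calibration
jitter (default sd 0.02 Da, ~5σ inside the 0.1 Da tolerance), intensities
log-normal, plus uniform decoy peaks over the acquisition window. Decoys
are excluded from ±0.2 Da (2 × tolerance) around *every* position of the
ladder comb above the lightest declared variant (n = 0..30), not merely
around planted rungs: a decoy landing on an unplanted rung position would
otherwise extend a ladder and conflate the sensitivity question (are
planted rungs recovered?) with the specificity question (are unrelated
peaks ignored?). A hostile mode instead parks decoys at half-rung offsets
to stress tie-breaking. No isotope envelopes or detector-noise physics are
simulated; absence-of-peak claims on real spectra are instrument- and
threshold-conditioned in ways the simulator does not capture, so passing
tests demonstrate correctness of the calling logic, not instrument-level
detectability.

## Problem sizes in the test suite

Property suites run at sizes where the independent oracles are exact and
fast: alignment oracle pairs of length ≤ 8 (200 pairs), motif oracle on
random sequences of length ≤ 50 (500 sequences × strict and fuzzy modes),
digestion properties on 500 random sequences ≤ 60 aa, and ladder recovery
on 100 seeded synthetic spectra of the 24-rung configuration. These sizes
prove the algorithms' contracts; the algorithms themselves are
size-independent.

## Known limitations

* Single-charge, monoisotopic model only; no isotopic envelope scoring.
* Motif matching is the discrete pattern as published, not an HMM/PSSM
  generalization; fuzzy mode is a bounded relaxation, not a learned model.
* Bridge classification ignores structural context entirely.
* Accessions in packaged metadata are labels; nothing is fetched from
  sequence databases.
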
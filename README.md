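# polygly

Interpretation of MALDI peptide-mass fingerprints for phosphorylation and
polyglycylation of 14-3-3 proteins, plus the sequence-level analyses that go
with them: signature-motif scanning, pairwise conservation statistics, and
salt-bridge based dimer-compatibility scoring.

## The problem

14-3-3 proteins are small, dimeric, acidic adaptors present in all
eukaryotes. In the intestinal parasite *Giardia duodenalis* the single
14-3-3 (g14-3-3) is constitutively phosphorylated on Thr214 and carries a
stage-dependent polyglycine chain on Glu246 — a polyglycylation otherwise
known mainly from tubulins. Both modifications are read out from MALDI-TOF
peptide mass fingerprints of tryptic digests:

* **phosphorylation** shifts a peptide's singly protonated monoisotopic
  mass (MH⁺) by **+79.96633 Da** on Ser/Thr/Tyr;
* **polyglycylation** appends *n* glycines to a glutamate side chain,
  producing a ladder of peaks at **MH⁺ + n × 57.02146 Da** — up to 24 rungs
  on the fully modified g14-3-3 C-terminal peptide.

This package computes the theoretical masses (in-silico tryptic digestion +
monoisotopic mass arithmetic), matches them to observed peak lists, calls
phospho shifts and 57-Da ladders, scans sequences for the proposed
polyglycylation signature motif

```
[T/G] X{0,1} [D/E] X{1,3} G [D/E] X{1,2} E{2,4}
```

(X polar or negatively charged; the terminal glutamate run carries the
candidate modification sites), and compares family members by global
alignment identity/similarity and by conservation of the N-terminal
salt bridges that stabilize 14-3-3 dimers (e.g. Arg18–Glu89, Glu5–Lys74,
Asp21–Lys85 in human 14-3-3ζ). A fully seeded synthetic-data module
generates peak lists and motif-bearing proteins with ground truth, so every
stage is testable without instrument data.

## Worked example

The phosphopeptide of g14-3-3 (residues 202–219, phospho-Thr214 = peptide
position 13):

```
$ polygly mass --peptide AFDAAITDLDKLTEESYK --phospho 13
peptide AFDAAITDLDKLTEESYK[phosphox1@13]
neutral 2108.96
mh_plus 2109.96
```

MH⁺ 2109.96 is the peak at which this peptide is observed exclusively in
its phosphorylated form. Simulating a fully polyglycylated C-terminal
peptide (rungs 1–24, no unmodified peak, 50 decoys, 0.02 Da calibration
jitter) and calling the ladder back:

```
$ polygly simulate --preset fig4c --seed 1 --out run/
$ polygly ladder --peaks run/peaks.tsv --base-mh 2105.93
{"base_mh": 2105.93, "step": 57.02146, "k_max": 24,
 "rungs": [1, 2, ..., 24], "gaps": [0], ...}
```

`k_max = 24` is the longest detected polyglycine chain; `gaps: [0]` records
that the unmodified peptide itself was absent — the fully modified state.
Ranking dimer partners of g14-3-3 by salt-bridge conservation:

```
$ polygly dimer --subject g14-3-3
partner_a   partner_b   intact  neutral repulsive   score
g14-3-3     LeoII       3       0       0           3
g14-3-3     g14-3-3     3       0       0           3
g14-3-3     D14-3-3e    1       1       1           0
```

The score (intact − repulsive bridges) ranks the Giardia homodimer and the
Giardia/LeoII heterodimer above the Giardia/D14-3-3ε pairing, which retains
a single bridge and gains a like-charge repulsion — matching the observed
dimerization preferences.

The same operations are available as a library
(`polygly.masscalc`, `polygly.digestion`, `polygly.spectra`,
`polygly.motif`, `polygly.conservation`, `polygly.dimer`,
`polygly.simulate`); see `docs/methods.md` for models, parameters and
conventions.

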
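# Methods

## Fragmentation chemistry and mass model

Sulfoxide-containing cleavable cross-linkers break at the C-S bond
adjacent to the central sulfoxide under CID, before backbone
fragmentation. The intact bridge contributes `alkene + sulfenic` to the
mass of a cross-linked pair; cleavage deposits the alkene (C₃H₂O,
54.010565 Da, identical for all four registered linkers) on the
NHS-ester/lysine side and the sulfenic acid on the other side. The
sulfenic acid routinely dehydrates to the thiol, so `thiol = sulfenic −
18.010565` is enforced as a registry invariant to 1e-6 Da. Registered
moieties:

| linker | sulfenic | thiol | symmetric | Cα–Cα max |
|---|---|---|---|---|
| DSSO    | C₃H₄O₂S (103.9932) | C₃H₂SO (85.9826) | yes | 30 Å |
| SDASO-L | C₇H₁₃NO₂S (175.0667) | C₇H₁₁NOS (157.0561) | no | 35 Å |
| SDASO-M | C₅H₁₀OS (118.0452) | C₅H₈S (100.0347) | no | 30 Å |
| SDASO-S | C₄H₈OS (104.0296) | C₄H₆S (86.0190) | no | 30 Å |

Monoisotopic atomic masses are hard-coded from the standard table to ≥6
decimals; proton = 1.00728 Da, water = 18.010565 Da. Printed nominal
labels (+54/+175/…) are treated as labels only; all arithmetic is at
full precision, and comparisons with printed m/z values round half-up to
2 decimals. New linkers can be registered from a config block without
code changes (`linker_from_dict`). The alkene/thiol doublet spacing used
for DSSO corroboration, thiol − alkene = 31.9721 Da, is a consequence of
the registry (S − O), not an independent constant.

One printed worked-example value is internally inconsistent: the
long-linker β_T of DLGEEHFK at 2+ is consistent with its parent mass and
thiol formula only at m/z 566.26, not the printed 556.26 (exactly 20 Da
low at 2+). We treat it as a typographical error and do not assert it.

## Digestion, decoys, candidates

Trypsin cleaves C-terminal to K/R, chymotrypsin C-terminal to F/W/Y/L,
neither before proline; defaults of 3 (trypsin) and 4 (chymotrypsin)
missed cleavages, peptide length 4–50. Digestion yields 1-based spans so
every identification stays mapped to protein coordinates. A
remnant-carrying lysine is treated as uncleaved: candidate alkene sites
must be internal unless the peptide ends at the protein C-terminus. The
protein N-terminal amine is not modeled as an NHS target. Decoys are
per-protein residue shuffles (seeded; reversal available) concatenated
to the targets, doubling the entry count. Side-B (diazirine) candidates
enumerate sulfenic or thiol on every residue the linker's second end can
target; candidate lookup is a binary search over a mass-sorted digest
index at ±20 ppm. Up to four variable modifications (carbamidomethyl-C,
oxidation-M, protein N-term acetyl, N-term pyroGlu) can be enumerated;
they are off by default in the synthetic workflow, which does not
generate them.

## Synthetic data generator

The generator is the study-conditions stand-in for a real acquisition.
Species: interlinks, NHS-hydrolyzed dead-ends (peptide attached via the
diazirine end; fragments carry thiol/sulfenic), diazirine-hydrolyzed
dead-ends (attached via NHS on lysine; fragments carry alkene), and
intralinks (single fragment carrying alkene + thiol). Dead-end species
add bridge + H₂O to the peptide mass. Counts are configurable with equal
dead-end/intralink defaults (no quantitative abundance ratio is
established for these species).

Lysine sites are drawn uniformly from digestible, remnant-eligible
lysines. Diazirine sites are drawn in two stages — residue type from the
normalized preference weights, then a uniform position of that type — so
the realized type fractions converge to the weights regardless of
database composition. The default profile plants glutamate at exactly
0.30 with A/D/L/Y moderately favored (0.072/0.068/0.073/0.064) and the
remaining 15 residues sharing the residual uniformly; the dominant-E
profile mirrors what diazirine chemistry shows empirically.

Rendering: each species gets one MS² spectrum (interlink: α_A at 100,
β_T at 80, β_S at 20 intensity units — a 1:4 sulfenic:thiol ratio, the
thiol being dominant; DSSO renders both assignment pairs plus both A/T
doublets) and data-dependent MS³ spectra of the up-to-four most intense
signal fragments, containing 1+ b/y ladders with −H₂O companions for
sulfenic precursors. Fragment charges split the precursor charge
(z_α = ⌊z/2⌋, z_β = z − z_α); precursor charges default to {3, 4, 5}, as
lower charge states are not selected for MS². Every m/z receives
multiplicative Gaussian error (σ in ppm, default 5) and each spectrum
gains 20 uniform low-intensity noise peaks by default. Intensities are
arbitrary units; isotope envelopes, chromatography and real intensity
physics are not emulated — so passing tests demonstrate correctness of
the identification logic and mass arithmetic, not robustness to
real-instrument artifacts. MGF files carry the scan lineage in TITLE
(`scan=<id> parent=<id> level=<n>`); seeded runs are byte-identical.

Toy structures: Cα-only multi-model PDB ensembles realize requested
per-model Cα–Cα distances exactly by placing each planted pair on its
own anchor, with unplanted residues on jittered per-chain baselines.
Planted K-side residues are lysines so the random-null machinery works
on the same files.

## Search and scoring

MS² pairing tests all peak pairs and charge splits (charges must sum to
the precursor charge — protons are conserved when the bridge cleaves)
against A+S = M and A+T = M − H₂O at ±20 ppm, keeping the best
hypothesis per pair. Pure-noise spectra produce a chance pair in ~2–4%
of cases at these settings; such pairs cannot become interlinks because
both MS³ constituents must also identify, and the per-spectrum
brute-force oracle in the tests pins the implementation exactly.

MS³ scoring is a binomial-tail score: with n theoretical b/y peaks
(neutral-loss companions included for sulfenic candidates), k matched
within ±0.6 Da, and per-peak chance probability p = 1.2 Da × observed
peak density, the score is −log₁₀ P(X ≥ k), X ~ Binomial(n, p).
Production search engines for this chemistry do not publish their
scoring functions, so this package defines its own: a deliberately
simple, rank-preserving statistic whose operating floor (default 5.0)
separates self-matches (scores ≳ 15 on
synthetic data) from shuffled decoys (≲ 1). Localization ambiguity
collects every remnant position of the same sequence within Δscore <
0.01 of the best; mass error, not intensity, is the only tiebreaker
anywhere.

## Assembly, FDR, collapse

An MS² precursor becomes an intralink if one child PSM carries
alkene + thiol and the precursor reconstructs within ±20 ppm; an
interlink if an alkene PSM and a sulfenic/thiol PSM jointly reconstruct
it and a signature pair covers their MS² peaks (the pair is then
oriented: A side = lysine peptide); otherwise a dead-end against the
bridge + H₂O model. Combined interlink score = min of the two
constituent scores (conservative). FDR = decoys/targets over the
score-ranked prefix at cross-link level; the filter keeps the largest
prefix within the threshold (default 1%) and reports the estimate as a
percentage. Collapse produces sequence-level keys (localization ignored)
and protein-coordinate K-X linkages with ambiguity intervals
(`X(128–131)` style); ambiguity-interval distances use the minimum over
the interval (most permissive). Replicate overlap reports all three
plausible readings — fraction of the union in ≥2 replicates, fraction in
all, and mean pairwise Jaccard — because a single "overlap" number is
ambiguous.

## Structural validation

Satisfaction is `distance ≤ max_ca_ca` (boundary satisfied), per model,
with unresolved residues excluded from the denominator. State-specific
classification over four models keeps linkages satisfied by a proper
non-empty subset and bins them into the 4 + 6 + 4 = 14 subset
categories; other model counts generalize to 2^n − 2 with a warning. The
random null enumerates Euclidean K→X distances (X = every other residue)
under a cap — 100 Å for single proteins, 300 Å for large complexes —
skipping solvent-path calculations; observed-vs-null comparison is a
two-sample Kolmogorov–Smirnov test — the question is only whether the
observed distances differ from random, so a distribution-free
two-sample test is the natural choice. Histograms use 5 Å bins. Subunit-to-chain mapping comes
from an explicit config; no sequence alignment to structures is
attempted.

## Preference statistic

Only diazirine-side constituents enter. Each identified peptide
contributes its ambiguity set of n sites; site x adds
`Wx = a_x,r / n` (priors a default to 1) to its residue type; `Px`
normalizes the totals to 1 (checked to 1e-9). Replicates/linkers are
pooled by default; per-linker tables can be computed by calling the
statistic per subset and averaging — both readings are defensible, and
pooling is the less variance-prone default. Localization precision is
reported as
the fraction of identifications with n = 1, 2, 3, ≥4.

## Problem sizes and numerical choices

Test and acceptance runs use a 12-protein × 320-residue synthetic
database: large enough that digest windows contain competing candidates
and decoys, small enough for tight iteration. The noisy end-to-end
property is exercised at 500 interlinks (5 ppm σ, 20 noise peaks) in the
test suite and at 300 interlinks in the acceptance script, with the
noiseless recovery check at 100; recovery and FDR are stable across
seeds at these sizes. The planted-preference check uses n = 2000
linkages, where the ±0.03 band is ≈3 binomial standard deviations.
Degenerate inputs fail loudly: empty databases, all-decoy FDR input,
MS³ scans without an MS² parent, structures without Cα atoms and
infeasible distance plans all raise with context rather than returning
defaults.

## Known limitations

No isotope envelopes, a/c/x/z ions, intensity modeling, retention time,
semi-specific digestion, open/offset searches or quantification.
Real-data concerns — co-isolation, deamidation-scale mass coincidences,
chromatographic irreproducibility across replicates — are outside what
the synthetic generator emulates, so the replicate-overlap metrics here
exercise bookkeeping, not biology. Structure mapping assumes the user
supplies the accession→chain mapping.
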
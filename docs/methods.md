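# Methods

## Assay model

A two-reaction allele-specific PCR assay for a biallelic SNP consists of a
common reverse primer and two forward allele-specific primers that differ
only at the 3′-terminal diagnostic base. Discrimination is sharpened
ARMS-style by an artificial destabilizing mismatch: the template base at
offset 4 from the diagnostic base (i.e. the 5th base from the 3′ terminus,
counting the terminus as position 1) is replaced by its Watson–Crick
complement. The substitution policy is strictly complement-of-template —
not the "strongest destabilizer" heuristics some ARMS designs use — because
that is the published design for all three CYP2C19 assays this package
reproduces: in each published forward primer the marked substitution is the
5th base from the 3′ end and is the complement of the flanking reference
base recoverable from the primer itself.

Amplification is modelled as a binary rule on the primer/template mismatch
profile: a reaction amplifies iff the profile has **no 3′-terminal mismatch
and at most one mismatch in total**. The matched allele (one internal
artificial mismatch) amplifies; the mismatched allele (terminal +
artificial, two mismatches) does not. This is a deliberate simplification:
the underlying chemistry is qualitative (a two-mismatch duplex is far less
extendable than a one-mismatch duplex), and the binary rule reproduces the
presence/absence gel readout exactly while remaining property-testable
(genotype → band-pattern mapping is injective, and adding mismatches can
never turn a non-amplifying reaction into an amplifying one). No
quantitative efficiency, Cq, polymerase-specific 3′-extension table, or
off-target priming is modelled. Whether a *lone* 3′-terminal mismatch
(without the artificial one) would amplify in practice is chemistry the
binary rule does not resolve; we treat any terminal mismatch as refractory.

## Design parameters

| parameter | default | rationale |
|---|---|---|
| artificial-mismatch offset | 4 (5th base from 3′) | matches all published primers |
| primer length | 18–25 nt | conventional PCR practice |
| Tm window (advisory) | 55–65 °C | compatible with 60 °C annealing |
| annealing target | 60 °C | published cycling conditions |
| product length | 80–400 bp | resolvable on a 2 % agarose gel |
| Na⁺ / primer conc. | 50 mM / 250 nM | standard nearest-neighbor conditions |
| GC fraction (reverse) | 0.30–0.70 | primer-design convention |
| 3′ G/C clamp (reverse) | required | primer-design convention |
| cycling | 94/60/72 °C, 30 s each, 35 cycles | published protocol |

Melting temperatures use Biopython's nearest-neighbor engine with the
unified Allawi & SantaLucia 1997 parameter table and the SantaLucia entropy
salt correction; oligos shorter than 8 nt fall back to the additive Wallace
rule (2 °C per A/T + 4 °C per G/C). The Tm window is advisory for forward
primers — the allele-specific primer is *defined* by its 3′ anchoring, so a
Tm outside the window is flagged on the primer record rather than fatal
(the published 22-mer at rs4244285 sits below 55 °C under these
conditions).

Forward-primer length is chosen within the allowed range (and the available
upstream context) to put the primer pair's mean Tm nearest the annealing
target, ties to the shorter primer. The reverse-primer search enumerates
all downstream windows satisfying length, GC, clamp and product-length
constraints and minimises |Tm − 60 °C|, ties to the shortest primer and
then the smallest amplicon. Both searches are deterministic.

## Fixture loci

The three CYP2C19 loci ship reconstructed from the published oligos alone:
the upstream flank is the published forward primer with the artificial
substitution reverted to its complement; the downstream flank is a
committed 150 bp synthetic spacer followed by the reverse complement of the
published common reverse primer. The true intervening genomic sequence and
product sizes are not part of the published assay description, so the
spacer is an explicitly synthetic stand-in; it is A/T-only so that, under
the GC-fraction and 3′-clamp constraints, no spacer-overlapping window can
out-score the embedded published binding site — which makes the published
reverse primers the unique optima of the documented objective and keeps the
round-trip regression deterministic. Consequently the fixture amplicon
lengths (192/192/189 bp) are properties of the fixture, not of the real
genomic assays, and the published reverse primers are regression anchors,
not evidence that they optimise any particular Tm criterion.

## Diplotype assembly

AS-PCR genotypes are unphased. Assembly places homozygous variants on both
haplotypes and heterozygous variants at different SNPs on opposite
haplotypes (*trans*), flagging the result `phased=False` whenever two
heterozygous variants forced that assumption — *2/*17 rather than
*1/*2+17-in-cis, which is the standard interpretation but not an
observation. Three simultaneous heterozygous variants raise an explicit
ambiguity error rather than an arbitrary cis pairing. When homozygosity
forces two variants onto one haplotype, the loss-of-function variant names
the allele (precedence *2 > *3 > *17), consistent with star-allele
nomenclature where the defining variant of a no-function allele dominates.

## Phenotype rules

The registry (`data/alleles.yaml`) assigns one function class per star
allele — *1 normal, *2/*3 none, *9 decreased, *17 increased, *12/*14
uncertain — and the phenotype depends only on the unordered pair of
classes, so the mapping is total and symmetric over all 28 registry pairs.
Any pair containing an uncertain-function allele is indeterminate
(uncertainty dominates, as the reference table's indeterminate row mixes
uncertain alleles with normal and no-function partners). Two decreased
alleles map to *likely intermediate*, following the reference table even
though some nomenclatures call *9/*9 intermediate. *9, *12 and *14 are
accepted as direct diplotype input but are not callable from the three-SNP
assay panel. The registry is data, not code: new alleles can be added with
a function class without touching the rule engine.

## Guidance knowledge base

`data/guidance_kb.yaml` is a curated lookup of published pediatric
recommendations, one record per printed value, each carrying a source-model
identifier and citation — explicitly *not* a PK simulator, and the
population-PK models behind the numbers are not re-derived. Choices made
where the sources are ambiguous:

- **Weight bands** (voriconazole maintenance, normal metabolizers
  16/12/10 mg/kg): printed as "(15 kg / 15–30 kg / 30 kg)", encoded
  half-open as <15, [15, 30), ≥30 kg so the lookup is total and
  deterministic.
- **Age bands** (twice-daily model): "younger/older than 12 years" encoded
  as <12 vs ≥12, with exactly-12 in the older band.
- **Percent adjustments** ("33–50 % lower", "25–50 % higher") are returned
  as dose intervals, never midpoints.
- **Rapid metabolizers** under the age-band model (published only for
  UM-or-EM vs PM-or-IM groups) are mapped to the UM/EM group with a caveat
  qualifier on the record.
- **Trough windows**: the default is 1.5–5.0 mg/L; the alternative
  1.0–5.5 mg/L window from a different monitoring study is selectable by
  name. Classification is strict outside the closed window.
- **"Likely" phenotypes** are grouped with their parent category
  (likely-poor with poor, likely-intermediate with intermediate) for dose
  lookup; indeterminate phenotypes get no dose and raise an error.
- Drug–drug interaction effects (omeprazole raises, rifampicin lowers the
  voriconazole trough) are emitted as qualitative flags only — no
  quantitative effect sizes are published.

Queries outside the published tables (e.g. an SSRI equivalent dose for an
intermediate metabolizer) raise rather than interpolate: the module's
contract is traceability, not coverage.

## Synthetic panels and what passing shows

`synth_panel` draws per-locus genotypes independently and uniformly
(defaults: 21 samples — the size of a typical reference-cell-line
validation set — uniform thirds per locus, seeded `random.Random`, no
hidden global state). This emulates a validation panel's *logical*
structure, not population genetics: no Hardy–Weinberg proportions, no
linkage disequilibrium between the three SNPs (real *2/*17 haplotype
frequencies are correlated), no assay noise, dropout or cross-
contamination. The 100 % simulate→call→assign concordance on these panels
therefore validates the *logic* — that the band-pattern encoding is
injective and the calling chain inverts the simulation exactly — and is the
package's synthetic stand-in for wet-lab concordance on reference cell
lines, for which no per-sample data are published. It says nothing about
wet-lab failure modes (weak bands, allele dropout), which are out of scope.
Acceptance runs use 26 exhaustive genotype combinations plus seeded panels
of 21 and 1000 samples; these sizes keep the full suite comfortably fast
while exercising every diplotype class many times over.

## Numerical and degenerate-input choices

Tm score comparisons are rounded to 9 decimal places before tie-breaking so
float noise cannot flip a deterministic tie. Diplotype equality ignores the
phasing flag (it is provenance, not identity). Band patterns carry a
product length iff at least one reaction amplified. Empty panels return
empty results; per-sample failures in batch calling are collected, not
fatal. Sequences are upper-cased on ingest; U (RNA) and IUPAC ambiguity
codes are rejected at the boundary.

## Known limitations

- The amplification rule is binary; it cannot rank partially-destabilized
  duplexes or model polymerase-specific 3′-mismatch extension.
- Reverse-primer design ignores secondary structure, hairpins and
  primer–dimer thermodynamics.
- Diplotype assembly covers the three-SNP panel; statistical phasing,
  copy-number and hybrid alleles, and the full star-allele catalog are out
  of scope.
- The guidance module encodes printed outputs of published models; it does
  not individualize doses (no Bayesian TDM) and is not a certified clinical
  decision-support tool.
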
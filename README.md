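# cyp2c19kit

Mismatch-augmented allele-specific PCR (AS-PCR / ARMS-style) genotyping for
**CYP2C19**, as a reusable assay-design and in-silico-simulation library,
coupled to a star-allele diplotype → metabolizer-phenotype translator and a
provenance-tracked pediatric dose-guidance knowledge base.

**Who it is for.** Labs running low-cost, single-patient CYP2C19 genotyping
(two plain PCR reactions per SNP, read on an agarose gel) and anyone who
needs to turn the resulting genotypes — or a VCF — into a CYP2C19
metabolizer phenotype and a literature-backed dose recommendation for
voriconazole, SSRIs, PPIs or clopidogrel in children.

## The method

For a biallelic SNP with major allele *M* and minor allele *m*, the assay
uses one common reverse primer and two forward allele-specific primers run
in two parallel reactions. Each forward primer

1. ends (3′ terminus) on the **diagnostic base** — the allele it targets —
   so extension on the other allele starts from a terminal mismatch; and
2. carries an **artificial destabilizing mismatch**: the template base at
   offset 4 from the diagnostic base (the 5th base from the 3′ end) is
   replaced by its Watson–Crick complement.

On the matched allele the duplex has a single internal mismatch and
amplifies; on the mismatched allele it has **two** mismatches (terminal
diagnostic + internal artificial) and is refractory. The two-reaction band
pattern then encodes the genotype injectively:

| genotype | major-allele reaction | minor-allele reaction |
|---|---|---|
| M/M | band | — |
| M/m | band | band |
| m/m | — | band |

The in-silico simulator encodes exactly this rule (amplify ⇔ no 3′-terminal
mismatch and ≤ 1 total mismatch). Three such assays at rs4244285 (\*2),
rs4986893 (\*3) and rs12248560 (\*17) give the star-allele diplotype under a
documented *trans* assumption for multi-SNP heterozygotes; the diplotype
maps to a metabolizer phenotype (ultra-rapid … poor, plus "likely" and
indeterminate categories) through a function-class rule table shipped as
data. Melting temperatures use the unified nearest-neighbor model
(Allawi & SantaLucia 1997; 50 mM Na⁺, 250 nM primer).

## Worked example

```python
>>> import cyp2c19kit as k
>>> assay = k.design_assay(k.table5_loci()[0])        # rs4244285 / CYP2C19*2
>>> assay.primer_major.sequence, assay.primer_minor.sequence
('CACTATCATTGATTATTACCCG', 'CACTATCATTGATTATTACCCA')
>>> assay.common_reverse.sequence, assay.product_length_bp
('CTCCATTTTGATCAGGAAGC', 192)
```

The two forward primers differ only at the 3′-terminal diagnostic base
(G targets the major allele, A the minor); both carry the artificial A
substitution five bases from the 3′ end; the amplicon is 192 bp on the
bundled fixture locus. Simulating and calling:

```python
>>> g = k.DiploidGenotypeAtLocus(assay.locus, ("major", "minor"))
>>> p = k.simulate_assay(assay, g)
>>> (p.major_reaction_amplified, p.minor_reaction_amplified)
(True, True)
>>> k.call_snp_genotype(p)
<GenotypeCall.HETEROZYGOUS: 'heterozygous'>
>>> d = k.Diplotype.from_string("*2/*17")
>>> k.diplotype_to_phenotype(d).phenotype
'intermediate'
>>> k.vcz_dose("takahashi-2021", "intermediate", weight_kg=10).dose_value
(8.0, 10.72)
```

The last call returns an *interval*: the source model prescribes a dose
33–50 % below the 16 mg/kg normal-metabolizer dose for a <15 kg child, and
the knowledge base never collapses published ranges to midpoints. Every
recommendation carries its source study and citation string.

The same pipeline is available from a shell:

```bash
cyp2c19kit design --out-dir out/                # published CYP2C19 assays
cyp2c19kit phenotype --diplotype "*2/*2"        # -> {"phenotype": "poor", ...}
cyp2c19kit recommend --drug voriconazole --model takahashi-2021 \
    --phenotype normal --weight 10              # -> 16 mg/kg record
cyp2c19kit fixtures --seed 1 --out-dir fx/      # synthetic 21-sample panel
cyp2c19kit call --vcf fx/panel.vcf --out diplotypes.tsv
```

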
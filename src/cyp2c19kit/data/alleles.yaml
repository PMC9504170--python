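# CYP2C19 star-allele function registry and diplotype -> phenotype rules.
#
# function classes: normal | decreased | none | increased | uncertain
# The rule table is keyed by the unordered pair of function classes; any
# pair containing an "uncertain" allele is indeterminate (uncertainty
# dominates), so only the ten certain-class pairs are listed.

allele_function:
  "*1": normal
  "*2": none
  "*3": none
  "*9": decreased
  "*12": uncertain
  "*14": uncertain
  "*17": increased

phenotype_rules:
  - classes: [increased, increased]
    phenotype: ultra-rapid
    rule: two increased function alleles
  - classes: [normal, increased]
    phenotype: rapid
    rule: one normal function allele and one increased function allele
  - classes: [normal, normal]
    phenotype: normal
    rule: two normal function alleles
  - classes: [normal, decreased]
    phenotype: likely-intermediate
    rule: one normal function allele and one decreased function allele
  - classes: [increased, decreased]
    phenotype: likely-intermediate
    rule: one increased function allele and one decreased function allele
  - classes: [decreased, decreased]
    phenotype: likely-intermediate
    rule: two decreased function alleles
  - classes: [normal, none]
    phenotype: intermediate
    rule: one normal function allele and one no function allele
  - classes: [increased, none]
    phenotype: intermediate
    rule: one increased function allele and one no function allele
  - classes: [decreased, none]
    phenotype: likely-poor
    rule: one decreased function allele and one no function allele
  - classes: [none, none]
    phenotype: poor
    rule: two no function alleles
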
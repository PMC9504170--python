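"""CYP2C19 diplotype -> metabolizer-phenotype translation.

Each registered star allele carries one function class (normal, decreased,
none, increased, uncertain); the predicted metabolizer phenotype depends
only on the unordered pair of function classes, so the rule engine is total
and symmetric over the registry.  Any pairing that involves an allele of
uncertain function is called indeterminate (uncertainty dominates).

The registry and rule table ship as a YAML data file so additional alleles
can be registered with a function class without code changes.  Alleles *9,
*12 and *14 are phenotype-resolvable but are not callable from the
three-SNP assay panel; they enter only as direct diplotype input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import combinations_with_replacement

import pandas as pd
import yaml

from .genotyping import Diplotype, _star_sort_key

__all__ = [
    "AlleleFunction",
    "PhenotypeCall",
    "RegistryError",
    "PHENOTYPE_ORDER",
    "load_registry",
    "allele_function",
    "diplotype_to_phenotype",
    "phenotype_table",
]

# activity-ordered, fastest first (used by guidance for monotonicity checks)
PHENOTYPE_ORDER = (
    "ultra-rapid",
    "rapid",
    "normal",
    "likely-intermediate",
    "intermediate",
    "likely-poor",
    "poor",
)

FUNCTION_CLASSES = ("normal", "decreased", "none", "increased", "uncertain")


class RegistryError(KeyError):
    """Unknown star allele."""


@dataclass(frozen=True)
class AlleleFunction:
    star_allele: str
    function_class: str


@dataclass(frozen=True)
class PhenotypeCall:
    phenotype: str
    rule: str


@lru_cache(maxsize=None)
def load_registry() -> tuple[dict[str, str], dict[frozenset, tuple[str, str]]]:
    """Load the allele-function registry and the class-pair rule table."""
    text = resources.files("cyp2c19kit").joinpath("data/alleles.yaml").read_text()
    raw = yaml.safe_load(text)
    registry = {str(k): str(v) for k, v in raw["allele_function"].items()}
    for star, cls in registry.items():
        if cls not in FUNCTION_CLASSES:
            raise ValueError(f"allele {star}: unknown function class {cls!r}")
    rules: dict[frozenset, tuple[str, str]] = {}
    for entry in raw["phenotype_rules"]:
        a, b = entry["classes"]
        rules[_pair_key(a, b)] = (entry["phenotype"], entry["rule"])
    return registry, rules


def _pair_key(class_a: str, class_b: str) -> frozenset:
    pair = (class_a, class_b)
    return frozenset({(c, pair.count(c)) for c in pair})


def allele_function(star_allele: str) -> AlleleFunction:
    """Function class of a registered star allele."""
    registry, _ = load_registry()
    star = star_allele.strip()
    if star not in registry:
        raise RegistryError(
            f"unknown star allele {star!r}; registered: {', '.join(sorted(registry, key=_star_sort_key))}"
        )
    return AlleleFunction(star, registry[star])


def diplotype_to_phenotype(d: Diplotype) -> PhenotypeCall:
    """Predicted metabolizer phenotype for a diplotype.

    Symmetric in the two alleles and total over the registry; a pair
    containing an uncertain-function allele is indeterminate.
    """
    _, rules = load_registry()
    fa = allele_function(d.alleles[0]).function_class
    fb = allele_function(d.alleles[1]).function_class
    if "uncertain" in (fa, fb):
        return PhenotypeCall("indeterminate", "one or two uncertain function alleles")
    phenotype, rule = rules[_pair_key(fa, fb)]
    return PhenotypeCall(phenotype, rule)


def phenotype_table() -> pd.DataFrame:
    """All unordered registry diplotypes with phenotype and applied rule."""
    registry, _ = load_registry()
    alleles = sorted(registry, key=_star_sort_key)
    rows = []
    for a, b in combinations_with_replacement(alleles, 2):
        call = diplotype_to_phenotype(Diplotype((a, b)))
        rows.append(
            {
                "diplotype": f"{a}/{b}",
                "function_pair": "/".join(sorted((registry[a], registry[b]))),
                "phenotype": call.phenotype,
                "rule": call.rule,
            }
        )
    return pd.DataFrame(rows)
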
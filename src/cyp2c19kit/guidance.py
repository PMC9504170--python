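"""Phenotype-conditioned dose guidance and risk flags (curated knowledge base).

This module is a provenance-tracked lookup over published pediatric dosing
recommendations for drugs cleared by CYP2C19 -- voriconazole (several
weight/age-based models and a prophylaxis policy), SSRI exposure-equivalent
doses, a voriconazole trough-concentration classifier, and qualitative risk
flags for PPIs, clopidogrel and SSRIs.  It is explicitly *not* a
pharmacokinetic simulator: every returned number comes from a knowledge-base
record carrying the source study identifier and a citation string, and
percent-adjustment recommendations are returned as intervals, never
collapsed to midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

from .genotyping import Diplotype
from .phenotype import PhenotypeCall

__all__ = [
    "GuidanceError",
    "DoseRecommendation",
    "TroughClassification",
    "RiskFlag",
    "load_knowledge_base",
    "vcz_dose",
    "classify_trough",
    "vcz_prophylaxis_policy",
    "ssri_equivalent_dose",
    "risk_flags",
    "comedication_flags",
]


class GuidanceError(ValueError):
    """Unknown model/drug or missing covariate for a guidance query."""


@dataclass(frozen=True)
class DoseRecommendation:
    """A dose recommendation with source-study provenance.

    ``dose_value`` is a single number, an ``(low, high)`` interval, or
    ``None`` when the recommendation is to avoid the drug (see
    ``qualifiers``).
    """

    drug: str
    source_model: str
    dose_value: float | tuple[float, float] | None
    units: str
    qualifiers: tuple[str, ...] = ()
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.citation:
            raise ValueError("every recommendation must carry a citation")


@dataclass(frozen=True)
class TroughClassification:
    concentration_mg_per_L: float
    window: tuple[float, float]
    classification: str  # subtherapeutic | therapeutic | supratherapeutic

    #: ordered classes, for monotonicity reasoning
    ORDER = ("subtherapeutic", "therapeutic", "supratherapeutic")


@dataclass(frozen=True)
class RiskFlag:
    drug_class: str
    condition: str
    flag_text: str
    citation: str


@lru_cache(maxsize=None)
def load_knowledge_base() -> dict:
    text = resources.files("cyp2c19kit").joinpath("data/guidance_kb.yaml").read_text()
    return yaml.safe_load(text)


def _phenotype_name(phenotype: PhenotypeCall | str) -> str:
    return phenotype.phenotype if isinstance(phenotype, PhenotypeCall) else str(phenotype)


_PM_IM = {"poor", "likely-poor", "intermediate", "likely-intermediate"}
_RM_UM = {"rapid", "ultra-rapid"}


def _scale(value, factor: float) -> float:
    return round(value * factor, 2)


def vcz_dose(
    model: str,
    phenotype: PhenotypeCall | str,
    weight_kg: float | None = None,
    age_years: float | None = None,
) -> DoseRecommendation:
    """Voriconazole dose recommendation under a named published model.

    Models and required covariates:

    * ``takahashi-2021`` (weight): normal-metabolizer base dose by weight
      band (<15 / 15-30 / >=30 kg -> 16 / 12 / 10 mg/kg), scaled by the
      published percent interval for PM/IM (33-50% lower) or RM/UM
      (25-50% higher).
    * ``tian-2021`` (age): twice-daily mg/kg dose by age band (<12 vs >=12
      years) and phenotype group (UM/EM vs PM/IM).
    * ``chen-2022``: median daily dose with published range, per NM/IM/PM
      group.
    * ``package-insert`` (age): age-banded weight-based label dose,
      phenotype-independent.
    """
    kb = load_knowledge_base()["voriconazole"]
    if model not in kb:
        raise GuidanceError(f"unknown voriconazole model {model!r}; known: {sorted(kb)}")
    rec = kb[model]
    pheno = _phenotype_name(phenotype)

    if model == "takahashi-2021":
        if weight_kg is None:
            raise GuidanceError("takahashi-2021 requires weight_kg")
        base = None
        for band in rec["normal_by_weight_band"]:
            if band["max_weight_kg"] is None or weight_kg < band["max_weight_kg"]:
                base = float(band["dose"])
                break
        assert base is not None
        qualifiers = [f"weight {weight_kg} kg", f"normal-metabolizer base dose {base} mg/kg"]
        if pheno in ("normal",):
            value: float | tuple[float, float] = base
        elif pheno in _PM_IM:
            lo, hi = rec["multipliers"]["poor_intermediate"]
            value = (_scale(base, lo), _scale(base, hi))
            qualifiers.append("33-50% lower than the normal-metabolizer dose")
        elif pheno in _RM_UM:
            lo, hi = rec["multipliers"]["rapid_ultrarapid"]
            value = (_scale(base, lo), _scale(base, hi))
            qualifiers.append("25-50% higher than the normal-metabolizer dose")
        else:
            raise GuidanceError(f"takahashi-2021 has no recommendation for phenotype {pheno!r}")
        return DoseRecommendation(
            "voriconazole", model, value, rec["units"], tuple(qualifiers), rec["citation"]
        )

    if model == "tian-2021":
        if age_years is None:
            raise GuidanceError("tian-2021 requires age_years")
        if pheno in _PM_IM:
            group = "pm_im"
        elif pheno in _RM_UM | {"normal"}:
            group = "um_em"
        else:
            raise GuidanceError(f"tian-2021 has no recommendation for phenotype {pheno!r}")
        band = "under_12_years" if age_years < 12 else "over_12_years"
        qualifiers = [f"age {age_years} years", f"phenotype group {group.upper()}"]
        if pheno == "rapid":
            qualifiers.append("rapid metabolizers mapped to the UM/EM group (model caveat)")
        return DoseRecommendation(
            "voriconazole",
            model,
            float(rec["groups"][group][band]),
            rec["units"],
            tuple(qualifiers),
            rec["citation"],
        )

    if model == "chen-2022":
        groups = rec["median_daily_dose"]
        mapping = {
            "normal": "normal",
            "intermediate": "intermediate",
            "likely-intermediate": "intermediate",
            "poor": "poor",
            "likely-poor": "poor",
        }
        if pheno not in mapping:
            raise GuidanceError(f"chen-2022 has no recommendation for phenotype {pheno!r}")
        entry = groups[mapping[pheno]]
        lo, hi = entry["range"]
        return DoseRecommendation(
            "voriconazole",
            model,
            float(entry["dose"]),
            rec["units"],
            (f"median daily dose; published range {lo}-{hi} mg/kg",),
            rec["citation"],
        )

    if model == "package-insert":
        if age_years is None:
            raise GuidanceError("package-insert dosing requires age_years")
        for band in rec["age_bands"]:
            if band["max_age_years"] is None or age_years < band["max_age_years"]:
                dose = band["dose"]
                value = tuple(float(x) for x in dose) if isinstance(dose, list) else float(dose)
                return DoseRecommendation(
                    "voriconazole", model, value, rec["units"], (band["note"],), rec["citation"]
                )
    raise AssertionError("unreachable")


def classify_trough(
    concentration_mg_per_L: float, window: str | tuple[float, float] = "standard"
) -> TroughClassification:
    """Classify a measured voriconazole trough against a target window.

    ``window`` is a named knowledge-base window (``standard`` = 1.5-5.0
    mg/L, ``garcia-garcia`` = 1.0-5.5 mg/L) or an explicit ``(low, high)``
    override.  Below the window is subtherapeutic (treatment-failure risk),
    above is supratherapeutic (adverse-effect risk).
    """
    if concentration_mg_per_L < 0:
        raise GuidanceError("trough concentration cannot be negative")
    if isinstance(window, str):
        windows = load_knowledge_base()["trough_windows"]
        if window not in windows:
            raise GuidanceError(f"unknown trough window {window!r}; known: {sorted(windows)}")
        lo, hi = windows[window]["window"]
    else:
        lo, hi = window
    if not lo < hi:
        raise GuidanceError("trough window must be ordered (low < high)")
    if concentration_mg_per_L < lo:
        cls = "subtherapeutic"
    elif concentration_mg_per_L > hi:
        cls = "supratherapeutic"
    else:
        cls = "therapeutic"
    return TroughClassification(concentration_mg_per_L, (float(lo), float(hi)), cls)


def vcz_prophylaxis_policy(phenotype: PhenotypeCall | str) -> DoseRecommendation:
    """Genotype-guided voriconazole prophylaxis policy.

    Rapid metabolizers receive an increased 300 mg twice-daily dose;
    ultra-rapid metabolizers should avoid voriconazole in favour of an
    alternative agent; everyone else receives the standard 200 mg
    twice-daily prophylactic dose.
    """
    kb = load_knowledge_base()["voriconazole"]["hicks-2020"]
    pheno = _phenotype_name(phenotype)
    policy = kb["prophylaxis"]
    if pheno == "ultra-rapid":
        return DoseRecommendation(
            "voriconazole",
            "hicks-2020",
            None,
            kb["units"],
            ("avoid voriconazole; use an alternative antifungal agent",),
            kb["citation"],
        )
    dose = policy.get(pheno, policy["default"])
    return DoseRecommendation(
        "voriconazole", "hicks-2020", float(dose), kb["units"], (), kb["citation"]
    )


def ssri_equivalent_dose(drug: str, phenotype: PhenotypeCall | str) -> DoseRecommendation:
    """SSRI dose giving exposure equivalent to the standard normal-metabolizer dose.

    Encoded for escitalopram (PM 10 / NM 20 / UM 30 mg/day, UM flagged for a
    twice-daily split) and sertraline (PM 100 / NM 150 / RM and UM 200
    mg/day).  Phenotypes without a published equivalent raise an error
    rather than interpolating.
    """
    kb = load_knowledge_base()["ssri"]["strawn-2019"]
    if drug not in ("escitalopram", "sertraline"):
        raise GuidanceError(f"unsupported drug {drug!r}; supported: escitalopram, sertraline")
    pheno = _phenotype_name(phenotype)
    table = kb[drug]
    if pheno not in table or pheno.endswith("_note"):
        raise GuidanceError(f"no published {drug} equivalent dose for phenotype {pheno!r}")
    qualifiers: tuple[str, ...] = ()
    if drug == "escitalopram" and pheno == "ultra-rapid":
        qualifiers = (table["ultra-rapid_note"],)
    return DoseRecommendation(
        drug, "strawn-2019", float(table[pheno]), kb["units"], qualifiers, kb["citation"]
    )


def risk_flags(
    drug_class: str,
    diplotype: Diplotype | None = None,
    phenotype: PhenotypeCall | str | None = None,
) -> list[RiskFlag]:
    """Qualitative risk flags whose phenotype/diplotype condition is met.

    PPI + *17 carrier -> reduced-exposure/therapy-failure flag;
    clopidogrel + poor/intermediate -> reduced active-metabolite flag
    (extrapolated from adults); SSRI + poor -> elevated adverse-effect
    flag.  Returns an empty list when no condition holds.
    """
    pheno = _phenotype_name(phenotype) if phenotype is not None else None
    out: list[RiskFlag] = []
    for entry in load_knowledge_base()["risk_flags"]:
        if entry["drug_class"] != drug_class:
            continue
        cond = entry["condition"]
        if cond == "star17_carrier":
            met = diplotype is not None and "*17" in diplotype.alleles
        elif cond == "poor_or_intermediate":
            met = pheno in _PM_IM
        elif cond == "poor":
            met = pheno in ("poor", "likely-poor")
        else:
            raise AssertionError(f"unknown condition {cond!r} in knowledge base")
        if met:
            out.append(RiskFlag(drug_class, cond, " ".join(entry["flag"].split()), entry["citation"]))
    return out


def comedication_flags(comedications: list[str]) -> list[RiskFlag]:
    """Qualitative voriconazole drug-drug interaction flags for co-medications."""
    wanted = {c.lower() for c in comedications}
    return [
        RiskFlag("voriconazole-comedication", entry["drug"], entry["effect"], entry["citation"])
        for entry in load_knowledge_base()["comedication_flags"]
        if entry["drug"].lower() in wanted
    ]
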
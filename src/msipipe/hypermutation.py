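"""Somatic-variant filtering and hypermutation classification.

Candidate somatic calls are filtered with the exome-study rules: the tumor
variant allele fraction must be at least 10%, common polymorphisms (a
dbSNP-style flag, pre-stripped of disease-associated entries) are removed,
and any variant present at an allele balance of 40% or more in a matched
germline sample is removed as inherited.  Specimens with more than 300
protein-altering somatic mutations after filtering are hypermutated.

PDX specimens lack a matched normal; in that mode only the common-variant
flag is applied and the resulting count is a novel-SNV (novSNV) count that
still contains residual germline variation, so it is reported separately
and deliberately not compared against the 300-mutation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "SomaticVariant",
    "BurdenResult",
    "PatientBurden",
    "filter_somatic",
    "classify_burden",
    "classify_cohort",
    "DEFAULT_VAF_MIN",
    "DEFAULT_GERMLINE_AB_MAX",
    "DEFAULT_BURDEN_THRESHOLD",
]

#: minimum tumor variant allele fraction, inclusive ("at least 10%")
DEFAULT_VAF_MIN = 0.10
#: germline allele balance at or above this is removed ("40% or more")
DEFAULT_GERMLINE_AB_MAX = 0.40
#: protein-altering burden strictly above this is hypermutated (">300")
DEFAULT_BURDEN_THRESHOLD = 300


@dataclass(frozen=True)
class SomaticVariant:
    """One candidate somatic call with tumor/normal support and consequence.

    ``pos`` is 1-based.  ``normal_allele_balance`` is the maximum allele
    balance observed across all germline samples of the patient.
    ``common_variant`` marks presence in a common-polymorphism database
    from which disease-associated entries were removed beforehand.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_vaf: float
    normal_allele_balance: float
    common_variant: bool
    protein_altering: bool
    consequence: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")


@dataclass
class BurdenResult:
    specimen_id: str
    n_input: int
    n_pass: int
    n_protein_altering: int
    hypermutated: bool

    def __post_init__(self) -> None:
        if not (self.n_protein_altering <= self.n_pass <= self.n_input):
            raise ValueError("require n_protein_altering <= n_pass <= n_input")


@dataclass
class PatientBurden:
    patient_id: str
    hypermutated: bool          # any-site rule
    concordant: bool            # all sites agree
    specimens: dict[str, BurdenResult]


def _fraction_ok(value: float) -> bool:
    return 0.0 <= value <= 1.0


def filter_somatic(
    variants: Iterable[SomaticVariant],
    vaf_min: float = DEFAULT_VAF_MIN,
    germline_ab_max: float = DEFAULT_GERMLINE_AB_MAX,
    matched_normal: bool = True,
) -> list[SomaticVariant]:
    """Apply the somatic filters; order-preserving and idempotent.

    Retains variants with ``tumor_vaf >= vaf_min``, ``common_variant``
    False and (when a matched normal exists) ``normal_allele_balance <
    germline_ab_max``.  With ``matched_normal=False`` (PDX mode) the
    allele-balance filter is disabled and only the common-variant database
    comparison applies.  Records with a fraction outside [0, 1] are
    rejected with a logged reason.
    """
    kept: list[SomaticVariant] = []
    for v in variants:
        if not _fraction_ok(v.tumor_vaf) or not _fraction_ok(v.normal_allele_balance):
            logger.warning(
                "rejecting malformed record %s:%d %s>%s (vaf=%r, nab=%r)",
                v.chrom, v.pos, v.ref, v.alt, v.tumor_vaf, v.normal_allele_balance,
            )
            continue
        if v.tumor_vaf < vaf_min:
            continue
        if v.common_variant:
            continue
        if matched_normal and v.normal_allele_balance >= germline_ab_max:
            continue
        kept.append(v)
    return kept


def classify_burden(
    variants: Sequence[SomaticVariant],
    specimen_id: str = "",
    threshold: int = DEFAULT_BURDEN_THRESHOLD,
    n_input: int | None = None,
) -> BurdenResult:
    """Classify an already-filtered variant list by protein-altering burden.

    ``hypermutated`` iff the protein-altering count strictly exceeds
    ``threshold``.  ``n_input`` may record the pre-filter count for
    bookkeeping; it defaults to the filtered count.
    """
    n_pass = len(variants)
    n_palt = sum(1 for v in variants if v.protein_altering)
    return BurdenResult(
        specimen_id=specimen_id,
        n_input=n_pass if n_input is None else n_input,
        n_pass=n_pass,
        n_protein_altering=n_palt,
        hypermutated=n_palt > threshold,
    )


def classify_cohort(
    burdens: Mapping[str, BurdenResult],
    specimen_to_patient: Mapping[str, str],
) -> dict[str, PatientBurden]:
    """Roll specimen-level burden calls up to patients.

    Patient-level hypermutation follows the any-site rule; the concordance
    flag records whether all of a patient's sites agree (trivially true for
    single-specimen patients).  A specimen without a patient mapping is an
    error.
    """
    per_patient: dict[str, dict[str, BurdenResult]] = {}
    for specimen_id, result in burdens.items():
        if specimen_id not in specimen_to_patient:
            raise ValueError(f"specimen {specimen_id!r} has no patient mapping")
        per_patient.setdefault(specimen_to_patient[specimen_id], {})[specimen_id] = result
    out: dict[str, PatientBurden] = {}
    for patient_id, specimens in per_patient.items():
        flags = [r.hypermutated for r in specimens.values()]
        out[patient_id] = PatientBurden(
            patient_id=patient_id,
            hypermutated=any(flags),
            concordant=len(set(flags)) == 1,
            specimens=specimens,
        )
    return out
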
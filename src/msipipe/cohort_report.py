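"""Patient-level cohort integration: prevalence, concordance, mechanism.

The two cohorts (PDX lines and rapid-autopsy patients) partially overlap:
some xenografts were derived from autopsy patients.  Prevalence therefore
collapses linked entries to unique patients before counting.  Concordance
checks that hypermutation status agrees across a patient's tumor sites.
The mechanism table cross-tabulates, per patient, hypermutation, MSI by
NGS and by PCR, and mismatch-repair gene lesions, and audits the expected
pattern: every hypermutated patient should be MSI positive and carry at
least one MMR lesion — departures are flagged, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientEntry",
    "CohortManifest",
    "PrevalenceResult",
    "ConcordanceResult",
    "unique_prevalence",
    "concordance",
    "mechanism_table",
]


@dataclass(frozen=True)
class PatientEntry:
    patient_id: str
    cohort: str                       # "PDX" or "autopsy"
    specimen_ids: tuple[str, ...]
    link: str | None = None           # PDX line -> source autopsy patient


@dataclass
class CohortManifest:
    entries: list[PatientEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            for sid in entry.specimen_ids:
                if sid in seen:
                    raise ValueError(f"duplicate specimen id {sid!r}")
                seen.add(sid)

    @classmethod
    def from_specs(cls, specs: Iterable) -> "CohortManifest":
        """Build from objects with patient_id/cohort/sites/link attributes
        (e.g. the synthetic generator's PatientSpec)."""
        entries = [
            PatientEntry(
                patient_id=s.patient_id,
                cohort=s.cohort,
                specimen_ids=tuple(f"{s.patient_id}|{site}" for site in s.sites),
                link=s.link,
            )
            for s in specs
        ]
        return cls(entries=entries)

    def specimen_to_patient(self) -> dict[str, str]:
        return {
            sid: e.patient_id for e in self.entries for sid in e.specimen_ids
        }


@dataclass
class PrevalenceResult:
    numerator: int
    denominator: int
    percent_exact: float
    percent_rounded: float            # one decimal, round-half-even
    discordant_groups: tuple[tuple[str, ...], ...]


@dataclass
class ConcordanceResult:
    per_patient: dict[str, bool]
    n_multisite: int
    rate: float                       # over multi-site patients; 1.0 vacuously
    discordant_patients: tuple[str, ...]


def _unique_groups(manifest: CohortManifest) -> list[tuple[str, ...]]:
    """Collapse linked cohort entries into unique-patient groups."""
    ids = {e.patient_id for e in manifest.entries}
    parent: dict[str, str] = {pid: pid for pid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for entry in manifest.entries:
        if entry.link is None:
            continue
        if entry.link not in ids:
            raise ValueError(
                f"{entry.patient_id}: link target {entry.link!r} not in manifest"
            )
        parent[find(entry.patient_id)] = find(entry.link)
    groups: dict[str, list[str]] = {}
    for pid in ids:
        groups.setdefault(find(pid), []).append(pid)
    return [tuple(sorted(members)) for members in groups.values()]


def unique_prevalence(
    manifest: CohortManifest, calls: Mapping[str, bool]
) -> PrevalenceResult:
    """Hypermutation prevalence over unique patients.

    ``calls`` maps every manifest entry id to its hypermutation call.
    Linked PDX/autopsy entries collapse into one unique patient counted
    once; a group with discordant calls counts as hypermutated (any-entry
    rule) and is flagged.  The percent is reported both exactly and
    rounded to one decimal (round-half-even).
    """
    for entry in manifest.entries:
        if entry.patient_id not in calls:
            raise ValueError(f"no hypermutation call for {entry.patient_id!r}")
    groups = _unique_groups(manifest)
    numerator = sum(1 for g in groups if any(calls[pid] for pid in g))
    denominator = len(groups)
    discordant = tuple(
        g for g in groups if len({calls[pid] for pid in g}) > 1
    )
    exact = 100.0 * numerator / denominator if denominator else float("nan")
    return PrevalenceResult(
        numerator=numerator,
        denominator=denominator,
        percent_exact=exact,
        percent_rounded=round(exact, 1) if denominator else float("nan"),
        discordant_groups=discordant,
    )


def concordance(
    specimen_calls: Mapping[str, bool],
    specimen_to_patient: Mapping[str, str],
) -> ConcordanceResult:
    """Per-patient agreement of specimen-level calls across tumor sites.

    The cohort rate is the fraction of multi-site patients whose sites all
    agree; with no multi-site patients it is vacuously 1.0 and
    ``n_multisite`` is 0 so callers can flag the vacuity.
    """
    by_patient: dict[str, list[bool]] = {}
    for sid, call in specimen_calls.items():
        by_patient.setdefault(specimen_to_patient[sid], []).append(call)
    per_patient = {pid: len(set(v)) == 1 for pid, v in by_patient.items()}
    multisite = [pid for pid, v in by_patient.items() if len(v) > 1]
    n_agree = sum(1 for pid in multisite if per_patient[pid])
    rate = n_agree / len(multisite) if multisite else 1.0
    return ConcordanceResult(
        per_patient=per_patient,
        n_multisite=len(multisite),
        rate=rate,
        discordant_patients=tuple(
            sorted(pid for pid in multisite if not per_patient[pid])
        ),
    )


def mechanism_table(
    hypermutated: Mapping[str, bool],
    msi_ngs_call: Mapping[str, str],
    msi_pcr_call: Mapping[str, str],
    lesion_sets: Mapping[str, Sequence],
) -> pd.DataFrame:
    """One row per patient linking burden, MSI and MMR-lesion calls.

    ``lesion_sets`` maps patient -> iterable of GeneLesionSet.  A
    hypermutated patient lacking MSI (by NGS) or lacking any MMR lesion is
    flagged as a ``violation`` of the expected mechanism; patients with a
    missing input are marked ``incomplete`` and not audited.
    """
    patients = sorted(
        set(hypermutated) | set(msi_ngs_call) | set(msi_pcr_call) | set(lesion_sets)
    )
    rows = []
    for pid in patients:
        complete = (
            pid in hypermutated and pid in msi_ngs_call
            and pid in msi_pcr_call and pid in lesion_sets
        )
        lesions = list(lesion_sets.get(pid, []))
        genes_with_lesions = sorted(
            {ls.gene for ls in lesions if ls.events}
        )
        biallelic_genes = sorted(
            {ls.gene for ls in lesions if ls.zygosity_verdict == "biallelic"}
        )
        hyper = bool(hypermutated.get(pid, False))
        msi_pos = msi_ngs_call.get(pid) == "MSI-high"
        violation = complete and hyper and (not msi_pos or not genes_with_lesions)
        rows.append(
            {
                "patient_id": pid,
                "hypermutated": hyper,
                "msi_ngs": msi_ngs_call.get(pid, ""),
                "msi_pcr": msi_pcr_call.get(pid, ""),
                "mmr_genes_with_lesions": ",".join(genes_with_lesions),
                "biallelic_genes": ",".join(biallelic_genes),
                "incomplete": not complete,
                "violation": violation,
            }
        )
    columns = [
        "patient_id", "hypermutated", "msi_ngs", "msi_pcr",
        "mmr_genes_with_lesions", "biallelic_genes", "incomplete", "violation",
    ]
    return pd.DataFrame(rows, columns=columns)
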
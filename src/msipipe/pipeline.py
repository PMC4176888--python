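"""End-to-end composition of the callers over a specimen or a cohort.

This is the path the command-line interface and the reproduction script
use: microsatellite histograms are scored against a normal-control
baseline, somatic variants are filtered and counted, clipped reads and
exon depth ratios become structural-variant and copy-number lesions, and
everything rolls up to patient-level prevalence, concordance and the
hypermutation/MSI/MMR-lesion mechanism table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import cohort_report, hypermutation, mmr_lesions, msi_ngs, msi_pcr
from .genemodel import GeneModel, default_mmr_model
from .synthetic_data import CohortData, SpecimenData

__all__ = ["SpecimenReport", "CohortAnalysis", "analyze_specimen", "analyze_cohort"]

MMR_GENES = ("MSH2", "MSH6", "MLH1")


@dataclass
class SpecimenReport:
    specimen_id: str
    msi: msi_ngs.MsiResult
    burden: hypermutation.BurdenResult
    lesions: dict[str, mmr_lesions.GeneLesionSet]
    rearrangements: list[mmr_lesions.Rearrangement]
    cnv_segments: list[mmr_lesions.CnvSegment]


@dataclass
class CohortAnalysis:
    specimen_reports: dict[str, SpecimenReport]
    patient_hypermutated: dict[str, bool]
    patient_msi_ngs: dict[str, str]
    patient_msi_pcr: dict[str, str]
    patient_lesions: dict[str, list[mmr_lesions.GeneLesionSet]]
    prevalence: cohort_report.PrevalenceResult
    burden_concordance: cohort_report.ConcordanceResult
    mechanism: pd.DataFrame


def analyze_specimen(
    data: SpecimenData,
    baselines: Mapping[str, msi_ngs.LocusBaseline],
    gene_model: GeneModel | None = None,
    matched_normal: bool = True,
) -> SpecimenReport:
    """Run every caller on one specimen's inputs."""
    model = gene_model or default_mmr_model()
    statuses: dict[str, str] = {}
    for locus_id, hist in data.histograms.items():
        if locus_id not in baselines:
            continue
        statuses[locus_id] = msi_ngs.evaluate_locus(hist, baselines[locus_id])
    msi_result = msi_ngs.call_specimen(statuses)

    filtered = hypermutation.filter_somatic(
        data.variants, matched_normal=matched_normal
    )
    burden = hypermutation.classify_burden(
        filtered, specimen_id=data.truth.specimen_id, n_input=len(data.variants)
    )

    rearrangements = mmr_lesions.cluster_breakpoints(
        data.clipped_reads, gene_model=model
    )
    _, segments = mmr_lesions.call_exon_cnv(data.exon_depth)
    lesions = {
        gene: mmr_lesions.call_gene_lesions(
            gene, filtered, rearrangements, segments, gene_model=model
        )
        for gene in MMR_GENES
    }
    return SpecimenReport(
        specimen_id=data.truth.specimen_id,
        msi=msi_result,
        burden=burden,
        lesions=lesions,
        rearrangements=rearrangements,
        cnv_segments=segments,
    )


def _merge_lesions(
    reports: Sequence[SpecimenReport],
) -> list[mmr_lesions.GeneLesionSet]:
    """Union each gene's events across a patient's sites (site-private
    lesions are retained; duplicates collapse) and re-assess zygosity."""
    merged: list[mmr_lesions.GeneLesionSet] = []
    for gene in MMR_GENES:
        events: list[mmr_lesions.LesionEvent] = []
        for report in reports:
            events.extend(report.lesions[gene].events)
        events = list(dict.fromkeys(events))
        merged.append(
            mmr_lesions.GeneLesionSet(
                gene=gene,
                events=events,
                zygosity_verdict=mmr_lesions.assess_biallelic(events),
            )
        )
    return merged


def analyze_cohort(
    cohort: CohortData,
    baselines: Mapping[str, msi_ngs.LocusBaseline],
    pdx_prior_status: Mapping[str, bool] | None = None,
    gene_model: GeneModel | None = None,
) -> CohortAnalysis:
    """Analyze every specimen and integrate to patient level.

    Autopsy specimens have matched normals, so hypermutation is called
    from the filtered protein-altering burden (any-site rule).  PDX lines
    have no matched normal: their novSNV count is not compared to the
    burden threshold, and the patient-level flag is taken from
    ``pdx_prior_status`` (prior characterization), defaulting to False
    when absent.
    """
    model = gene_model or default_mmr_model()
    cohort_by_patient = {s.patient_id: s.cohort for s in cohort.specs}
    pdx_prior_status = pdx_prior_status or {}

    reports: dict[str, SpecimenReport] = {}
    for specimen_id, data in cohort.specimens.items():
        patient_id = cohort.specimen_to_patient[specimen_id]
        matched_normal = cohort_by_patient[patient_id] != "PDX"
        reports[specimen_id] = analyze_specimen(
            data, baselines, gene_model=model, matched_normal=matched_normal
        )

    by_patient: dict[str, list[SpecimenReport]] = {}
    for specimen_id, report in reports.items():
        by_patient.setdefault(
            cohort.specimen_to_patient[specimen_id], []
        ).append(report)

    patient_hyper: dict[str, bool] = {}
    patient_ngs: dict[str, str] = {}
    patient_pcr: dict[str, str] = {}
    patient_lesions: dict[str, list[mmr_lesions.GeneLesionSet]] = {}
    burden_calls: dict[str, bool] = {}
    for patient_id, patient_reports in by_patient.items():
        if cohort_by_patient[patient_id] == "PDX":
            patient_hyper[patient_id] = bool(pdx_prior_status.get(patient_id, False))
        else:
            patient_hyper[patient_id] = any(
                r.burden.hypermutated for r in patient_reports
            )
            for r in patient_reports:
                burden_calls[r.specimen_id] = r.burden.hypermutated
        calls = [r.msi.call for r in patient_reports]
        if any(c == "MSI-high" for c in calls):
            patient_ngs[patient_id] = "MSI-high"
        elif all(c == "indeterminate" for c in calls):
            patient_ngs[patient_id] = "indeterminate"
        else:
            patient_ngs[patient_id] = "MSI-negative"
        patient_pcr[patient_id] = msi_pcr.call_msi_pcr(
            list(cohort.pcr_profiles[patient_id].values())
        ).call
        patient_lesions[patient_id] = _merge_lesions(patient_reports)

    manifest = cohort_report.CohortManifest.from_specs(cohort.specs)
    prevalence = cohort_report.unique_prevalence(manifest, patient_hyper)
    conc = cohort_report.concordance(
        burden_calls,
        {sid: cohort.specimen_to_patient[sid] for sid in burden_calls},
    )
    mechanism = cohort_report.mechanism_table(
        patient_hyper, patient_ngs, patient_pcr, patient_lesions
    )
    return CohortAnalysis(
        specimen_reports=reports,
        patient_hypermutated=patient_hyper,
        patient_msi_ngs=patient_ngs,
        patient_msi_pcr=patient_pcr,
        patient_lesions=patient_lesions,
        prevalence=prevalence,
        burden_concordance=conc,
        mechanism=mechanism,
    )
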
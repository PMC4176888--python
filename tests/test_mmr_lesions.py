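"""Tests for split-read clustering, exon CNV calling and zygosity verdicts."""

import numpy as np
import pandas as pd
import pytest

from msipipe.genemodel import default_mmr_model, msi_artifact_catalog
from msipipe.hypermutation import SomaticVariant
from msipipe.mmr_lesions import (
    ClippedRead,
    LesionEvent,
    assess_biallelic,
    call_exon_cnv,
    call_gene_lesions,
    cluster_breakpoints,
    exclude_msi_artifacts,
)


def _sv_reads(bp1, bp2, n=12, sides=("right", "right"), jitter=0, rng=None):
    reads = []
    for i in range(n):
        off = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        reads.append(ClippedRead(bp1[0], bp1[1] + off, sides[0], "+",
                                 bp2[0], bp2[1], "+"))
        off = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        reads.append(ClippedRead(bp2[0], bp2[1] + off, sides[1], "+",
                                 bp1[0], bp1[1], "+"))
    return reads


class TestClusterBreakpoints:
    def test_empty_input(self):
        assert cluster_breakpoints([]) == []

    def test_planted_inversion_recovered_exactly(self):
        reads = _sv_reads(("chr2", 47_640_000), ("chr2", 47_297_000), n=12)
        calls = cluster_breakpoints(reads, min_support=4, window=10)
        assert len(calls) == 1
        call = calls[0]
        assert call.type == "inversion"
        assert (call.bp1.pos, call.bp2.pos) == (47_297_000, 47_640_000)
        assert call.n_support == 12

    def test_planted_translocation_recovered(self):
        reads = _sv_reads(("chr2", 47_660_000), ("chr18", 48_000_000), n=8,
                          sides=("right", "left"))
        calls = cluster_breakpoints(reads)
        assert len(calls) == 1
        assert calls[0].type == "translocation"
        assert {calls[0].bp1.chrom, calls[0].bp2.chrom} == {"chr2", "chr18"}

    def test_underpowered_event_not_called(self):
        reads = _sv_reads(("chr2", 1000), ("chr2", 5000), n=2)
        assert cluster_breakpoints(reads, min_support=4) == []

    def test_jittered_positions_within_window(self):
        rng = np.random.default_rng(11)
        truth = (("chr2", 47_640_000), ("chr2", 47_297_000))
        reads = _sv_reads(*truth, n=12, jitter=5, rng=rng)
        calls = cluster_breakpoints(reads, min_support=4, window=10)
        assert len(calls) == 1
        recovered = sorted([calls[0].bp1.pos, calls[0].bp2.pos])
        for got, (_, want) in zip(recovered, sorted(truth, key=lambda b: b[1])):
            assert abs(got - want) <= 10

    def test_gene_annotation(self):
        reads = _sv_reads(("chr2", 47_640_000), ("chr2", 47_297_000), n=6)
        calls = cluster_breakpoints(reads, gene_model=default_mmr_model())
        assert calls[0].genes_hit == ("MSH2",)

    def test_two_nearby_events_stay_separate(self):
        reads = _sv_reads(("chr2", 47_700_000), ("chr2", 47_740_000), n=6)
        reads += _sv_reads(("chr2", 47_670_000), ("chr2", 47_744_000), n=6)
        calls = cluster_breakpoints(reads)
        assert len(calls) == 2


def _depth_frame(ratios_by_gene):
    rows = [
        {"gene": gene, "exon": i + 1, "depth_ratio": r}
        for gene, ratios in ratios_by_gene.items()
        for i, r in enumerate(ratios)
    ]
    return pd.DataFrame(rows)


class TestCallExonCnv:
    def test_all_neutral(self):
        calls, segments = call_exon_cnv(_depth_frame({"MSH2": [1.0] * 16}))
        assert all(c.state == "neutral" for c in calls)
        assert segments == []

    def test_partial_heterozygous_loss_segment(self):
        # exons 8-16 around half depth, exons 1-7 neutral
        ratios = [1.0] * 7 + [0.5] * 9
        _, segments = call_exon_cnv(_depth_frame({"MSH2": ratios}))
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.gene, seg.exon_start, seg.exon_end, seg.state) == (
            "MSH2", 8, 16, "loss")
        assert seg.label == "MSH2 exon 8-16 del"

    def test_homozygous_loss_covers_gene(self):
        _, segments = call_exon_cnv(_depth_frame({"MLH1": [0.03] * 19}))
        assert len(segments) == 1
        assert segments[0].state == "homozygous-loss"
        assert (segments[0].exon_start, segments[0].exon_end) == (1, 19)

    def test_single_exon_run_below_min_consecutive(self):
        ratios = [1.0, 0.5, 1.0, 1.0]
        _, segments = call_exon_cnv(_depth_frame({"MSH2": ratios}),
                                    min_consecutive=2)
        assert segments == []

    def test_row_order_invariance(self):
        df = _depth_frame({"MSH2": [1.0] * 7 + [0.5] * 9, "MLH1": [0.03] * 19})
        shuffled = df.sample(frac=1, random_state=3)
        a = call_exon_cnv(df)
        b = call_exon_cnv(shuffled)
        assert a == b

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            call_exon_cnv(_depth_frame({"MSH2": [-0.1]}))


def _tract_variant(tract, msi_status="MSI-high"):
    return SomaticVariant(
        chrom=tract.chrom, pos=tract.start + 5, ref="A", alt="AG",
        tumor_vaf=0.05, normal_allele_balance=0.0, common_variant=False,
        protein_altering=True, consequence="frameshift",
    )


class TestExcludeMsiArtifacts:
    def test_tract_variant_excluded(self):
        tract = msi_artifact_catalog()[0]
        retained, artifacts = exclude_msi_artifacts([_tract_variant(tract)])
        assert retained == [] and len(artifacts) == 1

    def test_variant_outside_tracts_retained(self):
        v = SomaticVariant("chr2", 47_640_001, "A", "AG", 0.3, 0.0, False, True,
                           "frameshift")
        retained, artifacts = exclude_msi_artifacts([v])
        assert retained == [v] and artifacts == []

    def test_exclusion_is_catalog_based_not_status_based(self):
        # the same tract variant is excluded whatever the specimen's MSI state
        tract = msi_artifact_catalog()[1]
        for status in ("MSI-high", "MSS"):
            retained, artifacts = exclude_msi_artifacts(
                [_tract_variant(tract, status)]
            )
            assert retained == [] and len(artifacts) == 1


FS = LesionEvent("frameshift", "chr2:47650001:A>AG")
FS2 = LesionEvent("frameshift", "chr2:47650500:C>CA")
INV1 = LesionEvent("rearrangement", "inversion chr2:47297000-chr2:47640000")
INV2 = LesionEvent("rearrangement", "inversion chr2:47670000-chr2:47744000")
HOM = LesionEvent("homozygous-loss", "MLH1 exon 1-19 homozygous del")
LOSS = LesionEvent("copy-loss", "MSH2 exon 8-16 del")


class TestAssessBiallelic:
    @pytest.mark.parametrize(
        "events, verdict",
        [
            ([], "none"),
            ([FS], "monoallelic"),
            ([HOM], "biallelic"),                 # homozygous loss alone
            ([FS, FS2], "biallelic"),
            ([INV1, INV2], "biallelic"),          # two gene-splitting inversions
            ([FS, LOSS], "biallelic"),
            ([FS, FS], "monoallelic"),            # duplicates count once
        ],
    )
    def test_verdicts(self, events, verdict):
        assert assess_biallelic(events) == verdict

    def test_adding_events_never_downgrades(self):
        order = {"none": 0, "monoallelic": 1, "biallelic": 2}
        events = []
        prev = assess_biallelic(events)
        for e in (FS, LOSS, INV1, HOM):
            events.append(e)
            now = assess_biallelic(events)
            assert order[now] >= order[prev]
            prev = now


class TestCallGeneLesions:
    def test_integrates_all_streams(self):
        model = default_mmr_model()
        variants = [
            SomaticVariant("chr2", 47_650_001, "A", "AG", 0.3, 0.0, False, True,
                           "frameshift"),
            _tract_variant(msi_artifact_catalog()[0]),  # must be set aside
        ]
        reads = _sv_reads(("chr2", 47_640_000), ("chr2", 47_297_000), n=6)
        rearrangements = cluster_breakpoints(reads, gene_model=model)
        _, segments = call_exon_cnv(
            _depth_frame({"MSH2": [1.0] * 7 + [0.5] * 9})
        )
        lesions = call_gene_lesions("MSH2", variants, rearrangements, segments,
                                    gene_model=model)
        kinds = sorted(e.kind for e in lesions.events)
        assert kinds == ["copy-loss", "frameshift", "rearrangement"]
        assert lesions.zygosity_verdict == "biallelic"

    def test_rearrangement_hitting_gene_twice_counts_once(self):
        model = default_mmr_model()
        # both breakpoints inside MSH2
        reads = _sv_reads(("chr2", 47_640_000), ("chr2", 47_700_100), n=6)
        rearrangements = cluster_breakpoints(reads, gene_model=model)
        lesions = call_gene_lesions("MSH2", [], rearrangements, [],
                                    gene_model=model)
        assert len(lesions.events) == 1
        assert lesions.zygosity_verdict == "monoallelic"
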
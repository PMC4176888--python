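"""Tests for the synthetic-data generator itself."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from msipipe import io, synthetic_data as sd
from msipipe.msi_ngs import MicrosatelliteLocus


LOCUS = MicrosatelliteLocus("T1", "chr1", 1000, 1025, "A", 25)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stutter_prob": 1.5},
            {"msi_locus_fraction": -0.1},
            {"n_loci": 0},
            {"depth_mean": 0},
            {"seed": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.SimulationConfig(**kwargs)


class TestLocusHistogram:
    def test_zero_noise_all_reads_at_reference(self):
        config = sd.SimulationConfig(seed=0, stutter_prob=0.0)
        hist = sd.simulate_locus_histogram(LOCUS, False, 100, config)
        assert hist.counts == {25: 100}

    def test_zero_depth_empty(self):
        config = sd.SimulationConfig(seed=0)
        hist = sd.simulate_locus_histogram(LOCUS, False, 0, config)
        assert hist.counts == {} and hist.depth == 0

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_locus_histogram(LOCUS, False, -1, sd.SimulationConfig())

    @pytest.mark.parametrize("depth", [100, 1000, 20000])
    def test_mass_conservation(self, depth):
        config = sd.SimulationConfig(seed=3)
        rng = np.random.default_rng(3)
        hist = sd.simulate_locus_histogram(LOCUS, True, depth, config, rng)
        assert hist.depth == depth

    def test_slipped_fraction_matches_analytic_form(self):
        """With stutter probability p, the analytic slip distribution is
        P(k slips) = (1-p) p^k; at depth 10^4 the observed fraction one unit
        below the reference must lie within 3 standard errors of it."""
        p, depth = 0.1, 10_000
        config = sd.SimulationConfig(seed=5, stutter_prob=p)
        rng = np.random.default_rng(5)
        hist = sd.simulate_locus_histogram(LOCUS, False, depth, config, rng)
        expected = (1 - p) * p  # analytic mass at reference - 1
        se = math.sqrt(expected * (1 - expected) / depth)
        observed = hist.counts.get(24, 0) / depth
        assert abs(observed - expected) < 3 * se

    def test_stutter_distribution_goodness_of_fit(self):
        """Chi-square GOF of the empirical slip distribution against the
        closed form, alpha=0.01, over 30 seeds: at most one rejection."""
        p, depth = 0.1, 50_000
        config = sd.SimulationConfig(seed=0, stutter_prob=p)
        rejections = 0
        for seed in range(30):
            rng = np.random.default_rng(seed + 1000)
            hist = sd.simulate_locus_histogram(LOCUS, False, depth, config, rng)
            # closed form computed here, independent of the generator's code
            probs = [(1 - p) * p**k for k in range(4)]
            probs.append(1.0 - sum(probs))  # lumped tail
            observed = [hist.counts.get(25 - k, 0) for k in range(4)]
            observed.append(depth - sum(observed))
            result = stats.chisquare(observed, [q * depth for q in probs])
            if result.pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_unstable_locus_gains_extra_allele_modes(self):
        """Destabilized loci carry more well-supported repeat lengths than
        stable ones (averaged over seeds; a drawn shift of one unit can hide
        inside the stutter tail on any single draw)."""
        config = sd.SimulationConfig(seed=0)

        def allele_count(unstable, seed):
            rng = np.random.default_rng(seed)
            hist = sd.simulate_locus_histogram(LOCUS, unstable, 20_000,
                                               config, rng)
            return sum(1 for c in hist.counts.values() if c >= 0.05 * hist.depth)

        stable = [allele_count(False, 200 + i) for i in range(30)]
        unstable = [allele_count(True, 200 + i) for i in range(30)]
        assert max(stable) <= 2
        assert max(unstable) >= 3
        assert np.mean(unstable) > np.mean(stable)


class TestSimulateSpecimen:
    def test_mss_specimen_only_contaminants(self, panel, config):
        truth = sd.SpecimenTruth("mss-0", "MSS", False, 0)
        data = sd.simulate_specimen(truth, panel, config)
        assert data.truth.destabilized_loci == ()
        assert all(
            v.tumor_vaf < 0.10 or v.normal_allele_balance >= 0.40 or v.common_variant
            for v in data.variants
        )

    def test_destabilized_count_is_half_the_panel(self, panel, config):
        truth = sd.SpecimenTruth("msi-0", "MSI-high", True, 100)
        data = sd.simulate_specimen(truth, panel, config)
        assert len(data.truth.destabilized_loci) == 73  # round(0.5 * 146)

    def test_planted_partial_deletion_shapes_depth_ratios(self, panel, config):
        lesion = sd.LesionSpec(kind="copy_loss", gene="MSH2",
                               label="MSH2 exon 8-16 del",
                               exon_start=8, exon_end=16, zygosity="het")
        truth = sd.SpecimenTruth("del-0", "MSS", False, 10, lesions=(lesion,))
        data = sd.simulate_specimen(truth, panel, config)
        msh2 = data.exon_depth[data.exon_depth.gene == "MSH2"].set_index("exon")
        assert (msh2.loc[8:16, "depth_ratio"] - 0.5).abs().max() < 0.2
        assert (msh2.loc[1:7, "depth_ratio"] - 1.0).abs().max() < 0.2

    def test_unknown_lesion_gene_rejected(self, panel, config):
        lesion = sd.LesionSpec(kind="frameshift", gene="PMS9", label="x")
        truth = sd.SpecimenTruth("bad", "MSS", False, 5, lesions=(lesion,))
        with pytest.raises(ValueError):
            sd.simulate_specimen(truth, panel, config)

    def test_empty_panel_rejected(self, config):
        truth = sd.SpecimenTruth("x", "MSS", False, 0)
        with pytest.raises(ValueError):
            sd.simulate_specimen(truth, [], config)

    def test_byte_identical_outputs_for_same_seed(self, panel, tmp_path):
        config = sd.SimulationConfig(seed=42)
        truth = sd.SpecimenTruth("det-0", "MSI-high", True, 80)
        paths = []
        for run in ("a", "b"):
            data = sd.simulate_specimen(truth, panel, config)
            out = tmp_path / f"hist_{run}.tsv"
            io.write_histograms_tsv(data.histograms, "det-0", out)
            var_out = tmp_path / f"var_{run}.tsv"
            io.write_variants_tsv(data.variants, var_out)
            paths.append((out, var_out))
        assert paths[0][0].read_bytes() == paths[1][0].read_bytes()
        assert paths[0][1].read_bytes() == paths[1][1].read_bytes()


class TestPcrProfiles:
    def test_stable_marker_modal_lengths_match(self):
        profile, shift = sd.simulate_pcr_profile("BAT-26", False, seed=4)
        assert shift is None
        t_mode = max(profile.tumor, key=profile.tumor.get)
        n_mode = max(profile.normal, key=profile.normal.get)
        assert t_mode == n_mode

    def test_unstable_marker_has_novel_shifted_peak(self):
        profile, shift = sd.simulate_pcr_profile("NR-24", True, seed=4)
        assert shift is not None and shift >= 3
        novel = sd.MARKER_REF_LENGTH["NR-24"] - shift
        assert profile.tumor[novel] >= 0.10 * max(profile.tumor.values())
        assert novel not in profile.normal or (
            profile.normal[novel] < 0.10 * max(profile.normal.values())
        )

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_pcr_profile("BAT-40", True, seed=0)

    def test_lucap58_fixture_unstable_set(self):
        _, truth = sd.simulate_marker_panel(sd.LUCAP58_UNSTABLE_MARKERS, seed=0)
        unstable = {m for m, s in truth.items() if s is not None}
        assert unstable == {"MONO-27", "BAT-25", "NR-24"}
        assert truth["NR-21"] is None and truth["BAT-26"] is None


class TestSimulateCohort:
    def test_empty_manifest_empty_outputs(self, config):
        cohort = sd.simulate_cohort([], config)
        assert cohort.specimens == {} and cohort.truths == {}

    def test_duplicate_specimen_ids_rejected(self, config, panel):
        spec = sd.PatientSpec("p1", "autopsy", ("liver", "liver"),
                              False, False, 10)
        with pytest.raises(ValueError):
            sd.simulate_cohort([spec], config, panel=panel)

    def test_study_design_counts(self):
        specs = sd.paper_cohort()
        pdx = [s for s in specs if s.cohort == "PDX"]
        autopsy = [s for s in specs if s.cohort == "autopsy"]
        assert len(pdx) == 15 and len(autopsy) == 50
        assert sum(s.hypermutated for s in pdx) == 3
        assert sum(s.hypermutated for s in autopsy) == 5
        assert sum(1 for s in pdx if s.link) == 5
        # exactly one link joins two hypermutated entries
        by_id = {s.patient_id: s for s in specs}
        hyper_links = [s for s in pdx if s.link and s.hypermutated
                       and by_id[s.link].hypermutated]
        assert len(hyper_links) == 1

    def test_site_private_lesion_differs_only_in_that_lesion(self, config, panel):
        private = sd.LesionSpec(kind="frameshift", gene="MLH1",
                                label="MLH1 frameshift (site-private)",
                                pos_offset=25_000, sites=("lymph node",))
        shared = sd.LesionSpec(kind="frameshift", gene="MSH2",
                               label="MSH2 frameshift (shared)", pos_offset=20_000)
        spec = sd.PatientSpec("p2", "autopsy", ("prostate", "lymph node"),
                              True, True, 400, lesions=(shared, private))
        cohort = sd.simulate_cohort([spec], config, panel=panel)
        t_pro = cohort.truths["p2|prostate"]
        t_lym = cohort.truths["p2|lymph node"]
        assert [l.label for l in t_pro.lesions] == [shared.label]
        assert [l.label for l in t_lym.lesions] == [shared.label, private.label]
        # everything else in the sidecar agrees
        d_pro = {k: v for k, v in t_pro.to_dict().items()
                 if k not in ("lesions", "specimen_id")}
        d_lym = {k: v for k, v in t_lym.to_dict().items()
                 if k not in ("lesions", "specimen_id")}
        assert d_pro == d_lym

    def test_multisite_truth_shared(self, config, panel):
        spec = sd.PatientSpec("p3", "autopsy", ("bone", "liver"),
                              True, True, 350)
        cohort = sd.simulate_cohort([spec], config, panel=panel)
        assert (
            cohort.truths["p3|bone"].destabilized_loci
            == cohort.truths["p3|liver"].destabilized_loci
        )
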
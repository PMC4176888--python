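import pytest

from msipipe import msi_ngs, pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def config():
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def panel():
    return sd.make_panel()


@pytest.fixture(scope="session")
def baselines(panel, config):
    return msi_ngs.train_baseline(sd.simulate_controls(panel, config))


@pytest.fixture(scope="session")
def cohort_analysis(panel, config, baselines):
    """Full study-design cohort, simulated and analyzed end to end."""
    specs = sd.paper_cohort()
    cohort = sd.simulate_cohort(specs, config, panel=panel)
    pdx_prior = {s.patient_id: s.hypermutated for s in specs if s.cohort == "PDX"}
    analysis = pipeline.analyze_cohort(cohort, baselines, pdx_prior)
    return specs, cohort, analysis


@pytest.fixture(scope="session")
def recovery_calls(panel, config, baselines):
    """MSI calls for 100 simulated MMR-deficient and 100 MMR-proficient
    specimens at default generator settings."""
    calls = {"MSI-high": [], "MSS": []}
    for status, burden in (("MSI-high", 400), ("MSS", 40)):
        for i in range(100):
            truth = sd.SpecimenTruth(
                specimen_id=f"recovery-{status}-{i:03d}",
                msi_status=status,
                hypermutated=status == "MSI-high",
                true_burden=burden,
            )
            data = sd.simulate_specimen(truth, panel, config)
            report = pipeline.analyze_specimen(data, baselines)
            calls[status].append(report.msi.call)
    return calls
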
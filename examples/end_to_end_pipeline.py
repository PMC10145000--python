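"""The full five-step release procedure on one simulated study.

capability -> capability limits -> stability -> expiry time -> ASTM region,
then three fresh batches are tested against the release criterion.
"""

from relcap import AnalysisConfig, ProcessScenario, SpecLimits, gen_stability, gen_time_zero, run_pipeline

config = AnalysisConfig(SpecLimits(1.454), bootstrap_reps=2000, seed=12345)
scenario = ProcessScenario(seed=12345, n_per_timepoint=2)

report = run_pipeline(
    assays=gen_time_zero(scenario),
    stability_data=gen_stability(scenario),
    config=config,
    new_batches=gen_time_zero(ProcessScenario(seed=777)),  # fresh batches
)
print(report.to_text())
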
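2026-10-02 05:01:49,090 INFO pipeline start: input=/tmp/pytest-of-root/pytest-2/test_fit_command_nonzero_exit_0/bad.csv seed=0 settings=FitSettings(max_iterations=500, rel_rss_tolerance=1e-10, step_tolerance=1e-12, damping_enabled=True, multistart_count=12, seed=0)
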
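"""One-call end-to-end run: generate, screen, fit, sensitivity, signal.

All stage outputs (CSV/JSON plus a Markdown report) land in the run
directory together with a manifest keyed by the config hash, so rerunning
the same config reproduces identical files.
"""

import json
import warnings

from pharmepi import study_config, run_pipeline

config = study_config(out_dir="scratch/example_run", seed=0)
config.survey = {"n_participants": 5_000}
config.reports["n_reports"] = 50_000

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    manifest = run_pipeline(config)

print("exposure OR by model tier:")
for tier, info in manifest["stages"]["fit"].items():
    print(f"  {tier}: {info['exposure_or']:.2f} "
          f"({info['ci'][0]:.2f}, {info['ci'][1]:.2f})")
print("sensitivity:", json.dumps(manifest["stages"]["sensitivity"], indent=2))
print("signals:", manifest["stages"]["signal"]["top_terms"])
print(f"outputs in {config.out_dir}/ — report.md has the human-readable summary")
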
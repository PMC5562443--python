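"""End-to-end synthetic pipeline run with a per-stage report.

Generates every input under out/inputs, runs all analysis stages, and
prints the stage summaries; a second run under the same seed reproduces
every output byte for byte.
"""

from pathlib import Path

from exitscape.pipeline import RunConfig, run

config = RunConfig(seed=1, out_dir=Path("scratch/example_run"))
results = run(config)
for stage, summary in results.items():
    print(f"{stage:>12s}: {summary}")
print(f"\nOutputs under {config.out_dir}/ carry provenance headers "
      "(tool version, seed, config digest); rerunning with the same seed "
      "reproduces them byte-identically.")
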
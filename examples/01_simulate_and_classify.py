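"""Generate a synthetic workspace and classify its putative enhancers.

Builds a small two-chromosome genome with 800 planted enhancer regions,
emits 4 noisy ChIP-seq replicate peak files per histone mark, runs the
consensus-merge + promoter-filter + presence-matrix classification, and
prints the per-state counts next to the planted truth.
"""

import tempfile
from pathlib import Path

from enhancerstates import SimulationConfig, generate_dataset, run_pipeline
from enhancerstates.simulate import truth_recovery_report

workdir = Path(tempfile.mkdtemp(prefix="enhancerstates_example_"))
config = SimulationConfig(seed=42)  # defaults: 4 samples/mark, 90% detection
workspace, truth = generate_dataset(config, workdir / "workspace")
result = run_pipeline(workspace.root, workdir / "out")

planted = {s.value: 0 for s in truth.regions_by_state()}
for pr in truth.regions:
    planted[pr.state.value] += 1

print(f"{'state':<15}{'planted':>8}{'called':>8}")
for state, n in result.state_counts.items():
    print(f"{state.value:<15}{planted.get(state.value, 0):>8}{n:>8}")

report = truth_recovery_report(truth, result.calls)
print(f"\noverall recall vs planted truth: {report['overall_recall']:.3f}")
print(
    "# called counts fall slightly below planted counts because each "
    "replicate\n# misses a true region with probability 0.1 and classes "
    "require >=3 of 4\n# detections; missed regions land in 'unclassified', "
    "never in a wrong class."
)
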
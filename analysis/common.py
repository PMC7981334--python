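"""Shared layout for the analysis drivers.

Heavy intermediates (per-subject scans, connectomes) live under
scratch/run; small summary tables go to results/.  All drivers share
one seeded configuration so the steps compose into a single study.
"""

from pathlib import Path

from fcaging.study import StudyConfig
from fcaging.workbench import RunConfig

SCRATCH = Path("scratch/run")
RESULTS = Path("results")
SEED = 1


def run_config(seed: int = SEED) -> RunConfig:
    RESULTS.mkdir(exist_ok=True)
    return RunConfig(outdir=str(SCRATCH), study=StudyConfig(seed=seed))
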
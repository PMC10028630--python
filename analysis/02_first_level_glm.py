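#!/usr/bin/env python
"""First-level GLM for every subject and experiment.

Fits voxel-wise OLS to each simulated BOLD run: the movie design (HRF-
convolved sexual and control annotation regressors plus drift) yields
per-subject sexual and control beta maps; the picture design (stick
functions per category) yields sexual-minus-landscape contrast maps.
"""

from pathlib import Path

from sexdecode.io import read_json
from sexdecode.pipeline import PipelineConfig, run_stage

HERE = Path(__file__).parent

config = PipelineConfig.load(HERE / "config.json")
manifest = run_stage("glm", config)
info = read_json(manifest)
print(f"glm: wrote {len(info['outputs'])} beta/contrast volumes")
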
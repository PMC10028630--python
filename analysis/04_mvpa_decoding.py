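#!/usr/bin/env python
"""Sex decoding: within-experiment LOSO, cross-experiment, control tests.

Runs the full multivariate protocol on the first-level maps: linear-kernel
leave-one-subject-out classification per experiment with a 499-shuffle
permutation null, radial-basis cross-experiment generalisation, the
control-dimension decoding and its cross-tests (expected at chance), and the
weight-map versus group-contrast correlation.
"""

import shutil
from pathlib import Path

from sexdecode.io import read_json
from sexdecode.pipeline import PipelineConfig, run_stage

HERE = Path(__file__).parent
RESULTS = HERE.parent / "results"

config = PipelineConfig.load(HERE / "config.json")
run_stage("mvpa", config)
RESULTS.mkdir(exist_ok=True)
src = Path(config.out_root) / "mvpa" / "mvpa_report.json"
shutil.copy(src, RESULTS / "mvpa_report.json")
report = read_json(src)
for key, val in report.items():
    if isinstance(val, dict) and "accuracy_pct" in val:
        flag = "significant" if val.get("significant") else "n.s."
        print(f"{key:28s} {val['accuracy_pct']:5.1f}%  "
              f"(null 95% = {val['null_q95_pct']:.1f}%, {flag})")
print(f"weight-contrast r: movie {report['weight_contrast_r_movie']:.2f}, "
      f"picture {report['weight_contrast_r_picture']:.2f}")
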
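#!/usr/bin/env python
"""Eye-tracking arm: saccade parsing, dynamic-ROI dwell, mixed model.

Parses every simulated gaze stream with the 30 deg/s + 4000 deg/s^2
detector, computes clip-wise proportional dwell per body-region ROI, and
fits the linear mixed model (ROI x actor sex x subject sex, per-subject
random intercept).  The planted pattern: male viewers dwell longer on the
female actor's chest (~7% vs ~5% of clip time).
"""

import shutil
from pathlib import Path

import pandas as pd

from sexdecode.eyetrack import dwell_group_model, dwell_sex_contrast
from sexdecode.pipeline import PipelineConfig, run_stage

HERE = Path(__file__).parent
RESULTS = HERE.parent / "results"

config = PipelineConfig.load(HERE / "config.json")
run_stage("eyetrack", config)
RESULTS.mkdir(exist_ok=True)
src = Path(config.out_root) / "eyetrack" / "dwell.tsv"
shutil.copy(src, RESULTS / "dwell.tsv")
dwell = pd.read_csv(src, sep="\t")

chest = dwell[(dwell.roi == "chest") & (dwell.actor_sex == "female")]
means = chest.groupby("subject_sex")["dwell_pct"].mean()
print("female-actor chest dwell: "
      f"male viewers {means.get('male', float('nan')):.1f}%  "
      f"female viewers {means.get('female', float('nan')):.1f}%")

fit, terms = dwell_group_model(dwell)
contrast = dwell_sex_contrast(fit, roi="chest", actor_sex="female")
print(f"chest (female actor) male-female LMM contrast: "
      f"{contrast['effect']:.2f} pp, z = {contrast['z']:.2f}, "
      f"p = {contrast['p_value']:.4f}")
terms.to_csv(RESULTS / "dwell_lmm_terms.tsv", sep="\t", index=False)
print(terms.to_string(index=False))
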
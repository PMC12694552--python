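"""Population statistics of the measured traits.

Writes the descriptive summary (min/max/mean/SD/CV/skewness/kurtosis/
Shapiro-Wilk) and the Pearson correlation matrix of the 15 traits.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import dataclasses

import pandas as pd

from milletct.pipeline import run_pipeline
from study_config import RESULTS, study_config

cfg = dataclasses.replace(study_config(), stages=("stats",))
run_pipeline(cfg)

summary = pd.read_csv(RESULTS / "summary.csv")
print(summary[["Trait", "Mean", "SD", "CV (%)", "Skewness", "Kurtosis",
               "Normal (rule)"]].round(4).to_string(index=False))
corr = pd.read_csv(RESULTS / "correlations.csv", index_col=0)
pairs = corr.stack()
pairs = pairs[pairs.index.get_level_values(0) < pairs.index.get_level_values(1)]
print("\nstrongest trait correlations:")
print(pairs.reindex(pairs.abs().sort_values(ascending=False).index).head(5).to_string())
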
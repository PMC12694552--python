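"""Shared configuration of the synthetic grain-structure study.

The study emulates a 100-line RIL population phenotyped by micro-CT:
30 lines are imaged (one grain each, mid-size phantoms so the whole imaging
track runs in a few minutes), while the QTL track uses the full 100-line
population with one planted locus on chromosome 2. All drivers write under
results/study/.
"""

from pathlib import Path

from milletct.phantom import PhantomSpec
from milletct.pipeline import RunConfig
from milletct.qtl import ScanParams

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"

SEED = 20210501  # sowing date of the emulated field trial


def study_config() -> RunConfig:
    return RunConfig(
        out_dir=str(RESULTS),
        seed=SEED,
        n_lines=40,
        grains_per_line=1,
        variation_cv=0.08,
        noise_sd_frac=0.05,
        heritability=0.6,
        geometry_coupling_cv=0.06,
        phantom=PhantomSpec(
            grain_semi_axes_um=(150.0, 120.0, 95.0),
            hull_thickness_um=12.0,
            cavity_gap_um=15.0,
        ),
        scan_params=ScanParams(n_permutations=200, seed=SEED),
        qtl_trait="K-Volume",
        n_genes=500,
        n_planted=7,
    )
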
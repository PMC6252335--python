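"""Shared configuration for the numbered analysis drivers.

The study cohort: K = 242 quasi-landmarks (22 x 11 paraboloid grid),
762 father-offspring pairs (the size of a well-powered parent-offspring
facial cohort after quality control), four planted modules with h2 =
0.8 / 0.6 / 0.4 / 0.2, covariate effects on age, sex and BMI, 1%
coordinate noise and nuisance rigid motions.  Each driver runs one
pipeline stage on the artifacts of the previous one.
"""

from faceherit.pipeline import PipelineConfig

OUTPUT_DIR = "results/analysis"


def study_config(seed: int = 20) -> PipelineConfig:
    return PipelineConfig(
        output_dir=OUTPUT_DIR,
        design={
            "grid_shape": (22, 11),
            "n_pairs": 762,
        },
        z_max=2.0,
        levels=5,
        pa_iters=100,
        n_perm=999,
        fwer=0.05,
        seed=seed,
        stability_sizes=[50, 100, 200, 400, 762],
        stability_reps=8,
    )
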
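#!/usr/bin/env python
"""Align, symmetrize, QC and covariate-adjust the simulated cohort.

GPA runs on originals + reflections combined; the symmetric component is
kept, outlier faces (z >= 2 on Procrustes distance to consensus) are
excluded pairwise, and age/sex/BMI effects are regressed out per cohort.
"""

import logging

from common import study_config

from faceherit.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    cfg = study_config()
    manifest = run_pipeline(cfg, stages=("preprocess",))
    info = manifest["stages"]["preprocess"]
    print(f"retained {info['n_pairs']} pairs ({info['n_excluded']} excluded by QC)")


if __name__ == "__main__":
    main()
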
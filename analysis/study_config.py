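"""Shared desk-scale study configuration for the numbered analysis drivers.

The drivers chain through ``scratch/study`` (volumes, sinograms — bulky
binary artifacts) and publish their tables under ``results/``.
"""

from petqa.pipeline import RunConfig

RUN_DIR = "scratch/study"
RESULTS_DIR = "results"

# Full design-matrix emulation at desk scale: NEMA on both scanners
# (6 PET-CT + 13 PET-MR reconstructions) and the Hoffman surrogate on the
# PET-MR (13 reconstructions), full beta grid 100..1000.
CONFIG = RunConfig(
    output_dir=RUN_DIR,
    seed=1,
    datasets=(
        ("F18_NEMA", "PET-CT"),
        ("F18_NEMA", "PET-MR"),
        ("F18_HOFFMAN", "PET-MR"),
    ),
    nema_shape=(80, 80, 24),
    nema_voxel_mm=(4.7, 4.7, 5.0),
    hoffman_shape=(96, 96, 32),
    hoffman_voxel_mm=(2.0, 2.0, 2.78),
    n_angles=192,
    total_counts=5.0e6,
    betas=tuple(float(b) for b in range(100, 1001, 100)),
    save_volumes=True,
    log_level="INFO",
)
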
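#!/usr/bin/env python
"""Reconstruct every simulated acquisition with its design-matrix rows.

PET-CT datasets get FBP and OSEM (5/10/15 mm post-filters); PET-MR datasets
get OSEM plus BSREM over the full beta grid (100..1000).  Volumes are
written to scratch/study named by nomenclature; an inventory with wall-clock
timings goes to results/recon_inventory.csv.
"""

import os
import sys
import time

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from study_config import CONFIG, RESULTS_DIR, RUN_DIR  # noqa: E402

from petqa.compare import build_recon_matrix  # noqa: E402
from petqa.recon import reconstruct  # noqa: E402
from petqa.volumes import Grid, read_sinogram, write_volume  # noqa: E402


def main() -> None:
    matrix = build_recon_matrix(list(CONFIG.datasets), betas=CONFIG.betas)
    rows = []
    for dataset, modality in CONFIG.datasets:
        tag = f"{dataset}_{modality.replace('-', '')}"
        sino = read_sinogram(os.path.join(RUN_DIR, f"{tag}_sino.bin"))
        shape = CONFIG.nema_shape if "NEMA" in dataset else CONFIG.hoffman_shape
        voxel = CONFIG.nema_voxel_mm if "NEMA" in dataset else CONFIG.hoffman_voxel_mm
        grid = Grid(shape, voxel)
        for cfg in matrix.configs_for(dataset, modality):
            t0 = time.time()
            rec = reconstruct(sino, cfg, grid)
            dt = time.time() - t0
            out = os.path.join(RUN_DIR, f"{tag}_{cfg.nomenclature}.nii")
            write_volume(rec, out)
            rows.append({"dataset": dataset, "modality": modality,
                         "recon": cfg.nomenclature, "algorithm": cfg.algorithm,
                         "seconds": round(dt, 2)})
            print(f"{tag} {cfg.nomenclature}: {dt:.1f} s")
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(RESULTS_DIR, "recon_inventory.csv"), index=False)
    print(f"reconstructed {len(rows)} volumes "
          f"({df.seconds.sum():.0f} s total) -> {RUN_DIR}")


if __name__ == "__main__":
    main()
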
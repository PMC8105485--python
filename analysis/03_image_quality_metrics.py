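#!/usr/bin/env python
"""Score every reconstruction with its phantom's image-quality metrics.

NEMA volumes: percentage contrast (hot and cold) and background variability
per sphere size.  Hoffman volumes: blur-matched FWHM (in-plane and axial),
axial uniformity (%SD over the right-putamen VOI) and SNR against the
zero-activity white-matter VOI.  The tidy table goes to results/metrics.csv.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from study_config import CONFIG, RESULTS_DIR, RUN_DIR  # noqa: E402

from petqa.compare import DATASET_PHANTOMS, build_recon_matrix, records_to_frame  # noqa: E402
from petqa.pipeline import analyze_volume, simulate_dataset  # noqa: E402
from petqa.volumes import read_volume  # noqa: E402


def main() -> None:
    matrix = build_recon_matrix(list(CONFIG.datasets), betas=CONFIG.betas)
    records = []
    for index, (dataset, modality) in enumerate(CONFIG.datasets):
        tag = f"{dataset}_{modality.replace('-', '')}"
        # regenerate phantom truth (labels + digital volume) deterministically
        _, spec, vol, labels, _ = simulate_dataset(CONFIG, dataset, index)
        for cfg in matrix.configs_for(dataset, modality):
            rec = read_volume(os.path.join(RUN_DIR, f"{tag}_{cfg.nomenclature}.nii"))
            recs = analyze_volume(CONFIG, dataset, modality, cfg.nomenclature,
                                  DATASET_PHANTOMS[dataset], rec, vol, labels, spec)
            for r in recs:
                sphere = f" [{r.sphere_diameter_mm:g} mm]" if r.sphere_diameter_mm else ""
                print(f"{tag} {cfg.nomenclature} {r.metric}{sphere} = {r.value:.3f}")
            records.extend(recs)
    df = records_to_frame(records)
    df.to_csv(os.path.join(RESULTS_DIR, "metrics.csv"), index=False)
    print(f"{len(df)} metric records -> {RESULTS_DIR}/metrics.csv")


if __name__ == "__main__":
    main()
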
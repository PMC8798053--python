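#!/usr/bin/env python
"""Preprocess the synthetic bioluminescence recordings.

Applies the standard chain per animal/experiment — linear detrend (offset
preserved), normalization to the overall mean, exclusion of the 5-min
pre-SD / 10-min post-SD margins, 30-min binning — and writes the cleaned
series under results/prep/.  Reports how many bins each masking step costs.
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]

from per2osc import io as pio
from per2osc.prep import preprocess_bioluminescence


def main() -> None:
    src = ROOT / "results" / "synthetic"
    dst = ROOT / "results" / "prep"
    dst.mkdir(parents=True, exist_ok=True)
    for exp_dir in sorted(src.iterdir()):
        if not (exp_dir / "bioluminescence.csv").exists():
            continue
        _, _, protocol = pio.load_experiment_config(
            exp_dir / "ground_truth.yaml")
        raw = pio.load_signal(exp_dir / "bioluminescence.csv")
        clean = preprocess_bioluminescence(raw, protocol)
        pio.save_signal(clean, dst / f"{exp_dir.name}_biolum_30min.csv")
        n_masked = int((~clean.valid).sum())
        print(f"{exp_dir.name}: {clean.n_bins} bins of "
              f"{clean.bin_width * 60:.0f} min, {n_masked} excluded around "
              f"{len(protocol.sd_intervals)} SDs, "
              f"mean of valid bins {np.mean(clean.valid_values()):.4f}")
    print(f"written to {dst}")


if __name__ == "__main__":
    main()
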
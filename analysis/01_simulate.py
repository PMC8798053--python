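#!/usr/bin/env python
"""Generate the three synthetic experiments used by the downstream analyses.

Emulates the in-vivo designs with known ground truth:

* ``scnx``  — behaviorally arrhythmic animal (no circadian modulation of
  the sleep-wake bouts), 2 baseline days, four daily 4-h sleep
  deprivations, one recovery day; oscillator driven with the
  lesioned-animal estimates.
* ``onoff`` — intact animal, 2 baseline days, 2 days of alternating 2-h
  sleep deprivations / sleep-opportunity windows, 2 recovery days;
  20-day warm-up, intact-animal circadian-force estimates.
* ``sixsd`` — intact animal, 2 baseline days, one 6-h sleep deprivation,
  2 recovery days; simulated with the intact-animal estimates (used to
  test out-of-sample prediction).

Writes hypnogram/LMA/bioluminescence CSVs plus a ground-truth sidecar per
experiment under results/synthetic/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from per2osc import io as pio
from per2osc.oscillator import OscillatorParams
from per2osc.protocols import repeated_4h_sd, six_hour_sd, two_h_on_off
from per2osc.synth import SynthConfig, generate_experiment

SCNX = OscillatorParams(gamma=0.0155, omega0=0.288, beta=6.81e-5,
                        intercept=0.92, A=2.92e-3, phi=4.73)
ONOFF = OscillatorParams(gamma=0.0155, omega0=0.288, beta=6.81e-5,
                         intercept=0.91, A=3.87e-3, phi=2.78)

EXPERIMENTS = {
    "scnx": dict(
        config=SynthConfig(duration_h=168.0, circadian_modulation=0.0,
                           noise_sd=0.02, seed=11),
        params=SCNX,
        protocol=repeated_4h_sd(baseline_h=48.0, n_days=4, recovery_h=24.0),
        use_warmup=False,
    ),
    "onoff": dict(
        config=SynthConfig(duration_h=144.0, circadian_modulation=0.8,
                           noise_sd=0.02, seed=13),
        params=ONOFF,
        protocol=two_h_on_off(baseline_h=48.0, recovery_h=48.0),
        use_warmup=True,
    ),
    "sixsd": dict(
        config=SynthConfig(duration_h=120.0, circadian_modulation=0.8,
                           noise_sd=0.02, seed=17),
        params=ONOFF,
        protocol=six_hour_sd(baseline_h=48.0, sd_len_h=6.0, recovery_h=66.0),
        use_warmup=True,
    ),
}


def main() -> None:
    out_root = ROOT / "results" / "synthetic"
    for name, kw in EXPERIMENTS.items():
        exp = generate_experiment(kw["config"], kw["params"], kw["protocol"],
                                  use_warmup=kw["use_warmup"])
        out = out_root / name
        out.mkdir(parents=True, exist_ok=True)
        pio.save_hypnogram(exp.epochs, out / "hypnogram.csv")
        pio.save_signal(exp.lma, out / "lma.csv")
        pio.save_signal(exp.biolum, out / "bioluminescence.csv")
        pio.save_experiment_config(out / "ground_truth.yaml", kw["config"],
                                   kw["params"], kw["protocol"])
        from per2osc.hypno import state_fractions
        f = state_fractions(exp.epochs)
        print(f"{name}: {exp.config.duration_h:.0f} h, "
              f"wake {100 * f['wake']:.1f}%, NREM {100 * f['nrem']:.1f}%, "
              f"REM {100 * f['rem']:.1f}%, "
              f"baseline mean LMA {exp.baseline_mean_lma:.1f} counts/6min "
              f"(SD imputation {2.4 * exp.baseline_mean_lma:.1f})")
    print(f"written to {out_root}")


if __name__ == "__main__":
    main()
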
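"""Simulate the study-sized spiral-drawing cohort.

Generates 138 PD-like and 150 control-like subjects (50 PD with disease
duration <= 5 years), ten spiral trials per hand at ~100 Hz, and writes the
cohort metadata, per-subject trace CSVs and the ground-truth parameter file
under scratch/cohort/.
"""

from pathlib import Path

import spiralkit as sk

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    manifest = sk.simulate_cohort(OUT, n_pd=138, n_control=150,
                                  n_early_pd=50, seed=sk.DEFAULT_SEED,
                                  trials_per_hand=10)
    print(f"cohort written to {OUT}")
    print(f"  {manifest['n_pd']} PD / {manifest['n_control']} controls, "
          f"{manifest['n_early_pd']} early PD, seed {manifest['seed']}")
    print(f"  {len(manifest['traces'])} subjects x 20 traces each")


if __name__ == "__main__":
    main()
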
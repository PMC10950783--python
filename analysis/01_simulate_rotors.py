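#!/usr/bin/env python
"""Generate a synthetic nanopore-array field of view.

Three driven rotors of known signed speed (two anticlockwise, one
clockwise, spanning the observed speed range) plus two non-rotating
controls: a slow extent-matched Brownian walker and a realistically fast
free diffuser. Writes the ThunderSTORM-style localization table and the
ground-truth manifest that 02_analyze_rotations.py tries to recover.
"""

import math
from pathlib import Path

from nanoturbine import io as nio
from nanoturbine import studies, synth

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901


def main() -> None:
    OUT.mkdir(exist_ok=True)
    acq = synth.AcquisitionParams()  # 8,000 frames at 200 fps, 15 nm noise
    rotors = [
        synth.RotorTruth(omega_d=2 * math.pi * 2.0, D_r=0.3, center=(0.0, 0.0)),
        synth.RotorTruth(omega_d=-2 * math.pi * 8.0, D_r=0.6, center=(1500.0, 0.0)),
        synth.RotorTruth(omega_d=2 * math.pi * 5.0, D_r=0.1, center=(0.0, 1500.0)),
    ]
    diffusers = [
        (studies.EXTENT_MATCHED_D_T, (1500.0, 1500.0)),
        (studies.FREE_D_T, (750.0, 750.0)),
    ]
    locs, manifest = synth.generate_array_dataset(rotors, diffusers, acq, seed=SEED)
    nio.write_localizations_csv(locs, OUT / "simulated_localizations.csv")
    nio.write_manifest(manifest, OUT / "simulated_truth_manifest.txt")
    print(f"{len(locs)} localizations from {len(manifest)} emitters")
    print(f"wrote {OUT / 'simulated_localizations.csv'}")
    print(f"wrote {OUT / 'simulated_truth_manifest.txt'}")


if __name__ == "__main__":
    main()
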
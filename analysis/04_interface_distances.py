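"""Measure inter-territory interface distances on paint phantoms.

Generates two-channel confocal phantoms with known inter-blob gaps,
runs the threshold -> split -> edge -> minimum-distance pipeline, and
compares the measured pairings against the phantom ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import territory_coupling as tc

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    corners = np.array(
        [[16, 16, 16], [16, 48, 48], [48, 16, 48], [48, 48, 16]], float
    )
    spacing = (0.2, 0.2, 0.2)
    diag = float(np.linalg.norm(spacing))
    rows = []
    for trial in range(10):
        centers = corners + rng.uniform(-5, 5, (4, 3))
        radii = rng.uniform(3, 9, 4)
        stack, truth = tc.generate_paint_stack(
            channels={
                "a": [tc.Sphere(tuple(centers[0]), radii[0]),
                      tc.Sphere(tuple(centers[1]), radii[1])],
                "b": [tc.Sphere(tuple(centers[2]), radii[2]),
                      tc.Sphere(tuple(centers[3]), radii[3])],
            },
            shape=(64, 64, 64),
            spacing=spacing,
            seed=SEED * 1000 + trial,
        )
        result = tc.pair_ipd(stack)
        got = sorted(result.distances.values())
        expected = sorted(truth["distances_um"].values())
        err = max(abs(m - e) for m, e in zip(got, expected))
        rows.append(
            dict(trial=trial, mean_um=result.mean, min_um=result.min,
                 max_abs_error_um=err)
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "interface_distances.tsv", sep="\t", index=False)
    print(f"10 phantoms: mean interface distance "
          f"{table['mean_um'].mean():.2f} um; worst measurement error "
          f"{table['max_abs_error_um'].max():.3f} um "
          f"(one voxel diagonal = {diag:.3f} um)")


if __name__ == "__main__":
    main()
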
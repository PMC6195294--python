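"""Six-axis pendulum identifiability on synthetic dogs.

Forward-simulates compound-pendulum sessions (composite and empty box
about xx, yy, zz and three 45-degree skew axes, three trials per axis)
for every segment of a virtual dog, then runs the full inversion
pipeline -- period estimation, pivot MoI, box subtraction, parallel-axis
correction, skew-axis product recovery -- and measures the error against
the known box-frame ground truth, noise-free and at 5% trace noise.

Writes results/pendulum_recovery.csv.
"""

import pathlib
import warnings

import numpy as np
import pandas as pd

from caninebsp.bsp_reference import AXIAL_SEGMENTS, SEGMENT_NAMES
from caninebsp.synthetic_data import (
    generate_dog,
    generate_pendulum_session,
    invert_session,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

KEYS = [n if n in AXIAL_SEGMENTS else f"left_{n}" for n in SEGMENT_NAMES]
N_SEEDS = 10


def tensor_error(rec, true):
    a = np.array([rec.i_xx, rec.i_yy, rec.i_zz, rec.p_xy, rec.p_xz, rec.p_yz])
    b = np.array([true.i_xx, true.i_yy, true.i_zz,
                  true.p_xy, true.p_xz, true.p_yz])
    return float(np.abs(a - b).max() / np.abs(b[:3]).max())


errors = {k: {"clean": [], "noisy": []} for k in KEYS}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for seed in range(N_SEEDS):
        dog = generate_dog(seed=seed)
        for label, noise in (("clean", 0.0), ("noisy", 0.05)):
            session = generate_pendulum_session(
                dog, noise=noise, seed=seed, segment_keys=KEYS
            )
            for k, s in session.segments.items():
                errors[k][label].append(tensor_error(invert_session(s),
                                                     s.true_tensor))

rows = [{
    "segment": k,
    "noise_free_max_err_pct": round(100 * max(v["clean"]), 5),
    "noisy_median_err_pct": round(100 * float(np.median(v["noisy"])), 3),
    "noisy_max_err_pct": round(100 * max(v["noisy"]), 3),
    "n_seeds": N_SEEDS,
} for k, v in errors.items()]
frame = pd.DataFrame(rows)
frame.to_csv(OUT / "pendulum_recovery.csv", index=False)
print(frame.to_string(index=False))

all_noisy = np.concatenate([v["noisy"] for v in errors.values()])
print(f"\nnoise-free sessions invert essentially exactly; at 5% trace noise "
      f"the median tensor error over {N_SEEDS} seeds x {len(KEYS)} segments is "
      f"{100 * float(np.median(all_noisy)):.3f}% (max "
      f"{100 * float(all_noisy.max()):.3f}%).")
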
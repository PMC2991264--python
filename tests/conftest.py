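import numpy as np
import pandas as pd
import pytest

from plaquedyn.synthetic import SimulationConfig, render_movie, simulate_tracks


@pytest.fixture(scope="session")
def small_truth():
    """Short wild-type-like simulation shared across tests."""
    return simulate_tracks(SimulationConfig(seed=7, n_frames=60))


@pytest.fixture(scope="session")
def grid_fixture():
    """Rendered movie of well-separated spots with known constituent counts.

    Spot spacing (3 µm) exceeds twice the patch radius so every object is
    resolvable; returns (stack, truth_table, pixel_size_um).
    """
    rng = np.random.default_rng(0)
    rows = []
    centers = [(x, y) for x in (-3.0, 0, 3.0) for y in (-3.0, 0, 3.0)]
    for frame in range(25):
        for i, (cx, cy) in enumerate(centers):
            rows.append(
                (
                    frame,
                    i,
                    cx + rng.uniform(-0.15, 0.15),
                    cy + rng.uniform(-0.15, 0.15),
                    int(rng.integers(1, 3)),
                )
            )
    df = pd.DataFrame(rows, columns=["frame", "track_id", "x_um", "y_um", "constituents"])
    stack, truth = render_movie(df, seed=3)
    return stack, truth, 0.1


def match_detections(truth_frame, det_frame, pixel_size_um, tol_um=0.5):
    """Greedy truth-to-detection matching within a distance tolerance.

    Returns (true_positives, false_positives, false_negatives, pairs)
    where pairs maps truth row index -> detection row index.
    """
    tx = truth_frame["col_px"].to_numpy() * pixel_size_um
    ty = truth_frame["row_px"].to_numpy() * pixel_size_um
    dx = det_frame["x_um"].to_numpy()
    dy = det_frame["y_um"].to_numpy()
    used = set()
    pairs = {}
    fn = 0
    for i in range(len(tx)):
        if len(dx):
            d = np.hypot(dx - tx[i], dy - ty[i])
            order = np.argsort(d)
            j = next((int(k) for k in order if k not in used and d[k] <= tol_um), None)
        else:
            j = None
        if j is None:
            fn += 1
        else:
            used.add(j)
            pairs[i] = j
    tp = len(pairs)
    fp = len(dx) - len(used)
    return tp, fp, fn, pairs
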
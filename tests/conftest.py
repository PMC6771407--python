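import numpy as np
import pandas as pd
import pytest

from hacscreen.simulate import IntensityModel, render_field


def match_centroids(
    truth: pd.DataFrame, detected: pd.DataFrame, max_dist: float = 5.0
) -> tuple[int, int, int, pd.DataFrame]:
    """Greedy nearest-neighbour matching of detected nuclei to ground truth.

    Returns (n_matched, n_truth_unmatched, n_detected_unmatched, pairs)
    where ``pairs`` joins matched truth/detected rows.
    """
    t_pts = truth[["row", "col"]].to_numpy(dtype=float)
    d_pts = detected[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    pairs = []
    used_d: set[int] = set()
    for ti in range(len(t_pts)):
        if len(d_pts) == 0:
            break
        dists = np.hypot(d_pts[:, 0] - t_pts[ti, 0], d_pts[:, 1] - t_pts[ti, 1])
        order = np.argsort(dists)
        for di in order:
            if dists[di] > max_dist:
                break
            if di not in used_d:
                used_d.add(int(di))
                pairs.append((ti, int(di), float(dists[di])))
                break
    matched = pd.DataFrame(
        [
            {
                **{f"truth_{k}": v for k, v in truth.iloc[ti].items()},
                **{f"det_{k}": v for k, v in detected.iloc[di].items()},
                "dist": dist,
            }
            for ti, di, dist in pairs
        ]
    )
    return (
        len(pairs),
        len(truth) - len(pairs),
        len(detected) - len(used_d),
        matched,
    )


@pytest.fixture(scope="session")
def small_field():
    """One clean 512x512 field: 20 interior nuclei, 60% GFP+, no planted
    QC-failure objects."""
    dapi, gfp, truth = render_field(
        0.6, n_nuclei=20, image_shape=(512, 512), seed=42
    )
    return dapi, gfp, truth


@pytest.fixture(scope="session")
def qc_field():
    """A field with planted border-touching and low-roundness objects."""
    dapi, gfp, truth = render_field(
        0.5,
        n_nuclei=15,
        image_shape=(512, 512),
        seed=7,
        n_border=4,
        n_irregular=3,
    )
    return dapi, gfp, truth
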
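import logging

import numpy as np
import pytest

import adenoquant as aq

logging.getLogger("adenoquant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study_table():
    """Default-condition synthetic feature table (study-scale)."""
    return aq.generate_table(aq.SynthTableSpec(seed=1))


@pytest.fixture(scope="session")
def study_design(study_table):
    """Design matrix, calls and mouse ids from the study-scale table."""
    spec = aq.default_spec(study_table)
    return aq.build_design_matrix(study_table, spec)


@pytest.fixture(scope="session")
def study_fit(study_design):
    """Full-dataset model, predictions and indicators."""
    X, y, mice = study_design
    model = aq.train_lda(X, y)
    calls, post = aq.predict(model, X)
    indicators = aq.compute_indicators(np.asarray(y), calls.to_numpy())
    return model, calls, post, indicators


def rasterize_ellipse(a: float, b: float, angle_deg: float = 0.0,
                      centre=(150.0, 150.0), shape=(300, 300)):
    """Pixel (rows, cols) inside an analytic ellipse.

    ``a``/``b`` are semi-axes in pixels; ``angle_deg`` is measured
    counter-clockwise from the x-axis with y pointing up (image rows
    increase downwards).
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols - centre[1]
    y = -(rows - centre[0])
    t = np.deg2rad(angle_deg)
    u = (x * np.cos(t) + y * np.sin(t)) / a
    v = (-x * np.sin(t) + y * np.cos(t)) / b
    inside = u**2 + v**2 <= 1.0
    return rows[inside], cols[inside]


def random_blob(rng: np.random.Generator, n_px: int = 200, shape=(80, 80)):
    """A random connected 8-connected blob grown from a seed pixel."""
    r0, c0 = shape[0] // 2, shape[1] // 2
    chosen = {(r0, c0)}
    frontier = [(r0, c0)]
    while len(chosen) < n_px and frontier:
        idx = rng.integers(len(frontier))
        r, c = frontier[idx]
        nbrs = [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
        nbrs = [p for p in nbrs if p not in chosen
                and 0 < p[0] < shape[0] - 1 and 0 < p[1] < shape[1] - 1]
        if not nbrs:
            frontier.pop(idx)
            continue
        p = nbrs[rng.integers(len(nbrs))]
        chosen.add(p)
        frontier.append(p)
    arr = np.array(sorted(chosen))
    return arr[:, 0], arr[:, 1]
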
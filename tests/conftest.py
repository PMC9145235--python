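import numpy as np
import pytest

from shankvb.imaging import analyze_section
from shankvb.synthetic import BundleSpec, SectionShapeSpec, generate_cross_section


@pytest.fixture(scope="session")
def small_scene():
    """A small round section (4 mm, 30 PZ + 40 IZ bundles) plus truth."""
    shape = SectionShapeSpec(outer_radius_mm=4.0)
    bundles = BundleSpec(pz_count=30, iz_count=40)
    img, truth = generate_cross_section(shape, bundles, seed=11)
    return img, truth


@pytest.fixture(scope="session")
def analyzed_scene(small_scene):
    """The small scene run through the full imaging pipeline."""
    img, truth = small_scene
    mask, part, det = analyze_section(img)
    return img, truth, mask, part, det


def brute_force_hull_area(points: np.ndarray) -> float:
    """Independent convex-hull oracle: O(n^3) one-sided-edge test.

    A directed edge (i, j) lies on the hull iff every other point is on
    or to the left of it; hull vertices are collected from such edges and
    the area follows from the shoelace formula.
    """
    pts = np.unique(np.asarray(points, float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    on_hull = np.zeros(n, bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e = pts[j] - pts[i]
            cross = e[0] * (pts[:, 1] - pts[i, 1]) - e[1] * (pts[:, 0] - pts[i, 0])
            if np.all(cross >= -1e-12):
                on_hull[i] = on_hull[j] = True
    hull = pts[on_hull]
    c = hull.mean(axis=0)
    ang = np.arctan2(hull[:, 1] - c[1], hull[:, 0] - c[0])
    hull = hull[np.argsort(ang)]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def random_blob(rng: np.random.Generator, n_px: int = 30) -> np.ndarray:
    """A connected random pixel blob grown from a seed pixel."""
    frontier = {(0, 0)}
    blob = set()
    while len(blob) < n_px and frontier:
        cand = sorted(frontier)
        pick = cand[rng.integers(len(cand))]
        frontier.discard(pick)
        blob.add(pick)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nxt = (pick[0] + dr, pick[1] + dc)
            if nxt not in blob:
                frontier.add(nxt)
    arr = np.array(sorted(blob))
    return arr - arr.min(axis=0)
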
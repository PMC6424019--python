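import numpy as np
import pytest

from lamellometry import Silhouette, datasets


@pytest.fixture(scope="session")
def unit_square():
    return Silhouette(polygon=np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))


@pytest.fixture(scope="session")
def plus_sign():
    """Three unit squares in a row plus one above and one below the centre."""
    verts = np.array(
        [
            [0, 1], [1, 1], [1, 0], [2, 0], [2, 1], [3, 1],
            [3, 2], [2, 2], [2, 3], [1, 3], [1, 2], [0, 2],
        ],
        float,
    )
    return Silhouette(polygon=verts)


@pytest.fixture(scope="session")
def study_table():
    return datasets.load_measurements()


@pytest.fixture(scope="session")
def study_tree():
    return datasets.load_tree()


@pytest.fixture(scope="session")
def trait_matrix():
    return datasets.load_trait_matrix()


def ribbon_mask(length=100, width=5, pad=8):
    m = np.zeros((width + 2 * pad, length + 2 * pad), dtype=bool)
    m[pad : pad + width, pad : pad + length] = True
    return m


def y_mask(arm=50, half_w=2):
    """Y-shaped ribbon: three arms meeting at one point."""
    import skimage.draw as skd

    n = 2 * arm + 20
    m = np.zeros((n, n), dtype=bool)
    c = n // 2
    for ang in (180, 45, -45):
        r2 = c + int(round(arm * np.sin(np.radians(ang))))
        c2 = c + int(round(arm * np.cos(np.radians(ang))))
        rr, cc = skd.line(c, c, r2, c2)
        for dr in range(-half_w, half_w + 1):
            m[np.clip(rr + dr, 0, n - 1), cc] = True
    return m


def h_mask(arm=40, half_w=2):
    """H-shaped ribbon: two verticals joined by a crossbar (2 junctions)."""
    import skimage.draw as skd

    n = 2 * arm + 30
    m = np.zeros((n, n), dtype=bool)
    x1, x2 = 20, n - 20
    for x in (x1, x2):
        rr, cc = skd.line(15, x, n - 15, x)
        for dc in range(-half_w, half_w + 1):
            m[rr, np.clip(cc + dc, 0, n - 1)] = True
    rr, cc = skd.line(n // 2, x1, n // 2, x2)
    for dr in range(-half_w, half_w + 1):
        m[np.clip(rr + dr, 0, n - 1), cc] = True
    return m


def brute_force_branches(skel: np.ndarray) -> int:
    """Independent branch count: drop node pixels, count what remains.

    A node pixel has 1 or >= 3 skeleton neighbours (endpoint / junction).
    Removing junction pixels (merging 8-adjacent ones implicitly) splits the
    skeleton into its branch paths, counted as connected components, plus one
    edge for every junction-junction adjacency severed.
    """
    from scipy import ndimage

    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    counts = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    junctions = skel & (counts >= 3)
    rest = skel & ~junctions
    _, n = ndimage.label(rest, structure=np.ones((3, 3)))
    # adjacent junction clusters connected directly to each other
    lab_j, n_j = ndimage.label(junctions, structure=np.ones((3, 3)))
    direct = 0
    for a in range(1, n_j + 1):
        grown = ndimage.binary_dilation(lab_j == a, structure=np.ones((3, 3)))
        for b in range(a + 1, n_j + 1):
            if (grown & (lab_j == b)).any():
                direct += 1
    return n + direct
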
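import numpy as np
import pytest

from fadyn.simulate import AcquisitionSpec, simulate_cell_mask

#: Compact acquisition used by unit tests: same calibration as the full
#: studies but a smaller field holding a 40 x 28 um cell.
SMALL_ACQ = AcquisitionSpec(
    n_frames=60,
    frame_interval=1.0,
    pixel_size=0.16,
    image_shape=(390, 540),
    psf_sigma=0.16,
    background_level=10.0,
)


@pytest.fixture(scope="session")
def ellipse_cell():
    """25 x 15 um semi-axis ellipse at 0.2 um/px."""
    return simulate_cell_mask((200, 320), 0.2, "ellipse", {"semi_axes": (25.0, 15.0)})


@pytest.fixture(scope="session")
def small_cell():
    """40 x 28 um semi-axis ellipse matching SMALL_ACQ."""
    return simulate_cell_mask(SMALL_ACQ.image_shape, SMALL_ACQ.pixel_size,
                              "ellipse", {"semi_axes": (40.0, 28.0)})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def flood_fill_count(mask: np.ndarray, connectivity: int = 2) -> int:
    """Brute-force 8- (or 4-) connected component count by BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    count = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def brute_force_central(cell: np.ndarray, band_px: float) -> np.ndarray:
    """O(N^2) min-distance central mask: integer squared distances from every
    foreground pixel centre to every background pixel centre, compared with
    (band_px + 0.5)^2 (the half-pixel boundary offset)."""
    cell = np.asarray(cell, dtype=bool)
    fg = np.argwhere(cell)
    bg = np.argwhere(~cell)
    thr2 = (band_px + 0.5) ** 2
    central = np.zeros_like(cell)
    for r, c in fg:
        d2 = np.min((bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2)
        if d2 >= thr2:
            central[r, c] = True
    return central
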
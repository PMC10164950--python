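import numpy as np
import pytest

import organoidseg as og


@pytest.fixture(scope="session")
def overfit_tiles():
    """Eight 96x96 synthetic organoid tiles used for overfit/training checks."""
    return [
        og.generate_synthetic_scene(
            og.SyntheticSceneSpec(
                width=96, height=96, n_organoids=3, radius_range=(8, 18),
                intensity_contrast=0.6, noise_sigma=5.0,
                illumination_amplitude=0.1, seed=100 + i,
            )
        )
        for i in range(8)
    ]


@pytest.fixture(scope="session")
def tiny_cfg():
    """Very small network (channels / 16) for fast structural tests."""
    return og.default_network_config(width_divisor=16, input_hw=(64, 64))


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    """Read-only tiny model; tests that mutate weights build their own."""
    return og.assemble_acu2net(tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def trained_tiny(overfit_tiles):
    """A briefly trained small model (used by inference sanity checks)."""
    cfg = og.small_network_config(input_hw=(96, 96))
    model = og.assemble_acu2net(cfg, seed=0)
    tc = og.TrainConfig(epochs=150, learning_rate=0.02, momentum=0.9,
                        batch_size=8, seed=0, stop_at_val_f1=0.9)
    best, logs = og.train(model, overfit_tiles, overfit_tiles, tc)
    return og.restore_model(best), best, logs


def brute_force_point_in_polygon(x: float, y: float, verts) -> bool:
    """Boundary-inclusive even-odd test, independent of the implementation."""
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if (
            abs(cross) < 1e-9
            and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9
            and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9
        ):
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def random_simple_polygon(rng: np.random.Generator, canvas: int):
    """Star-shaped (hence simple) polygon with float vertices on the canvas."""
    k = int(rng.integers(3, 9))
    cx, cy = rng.uniform(canvas * 0.3, canvas * 0.7, 2)
    angles = np.sort(rng.uniform(0, 2 * np.pi, k))
    radii = rng.uniform(canvas * 0.1, canvas * 0.45, k)
    xs = np.clip(cx + radii * np.cos(angles), 0, canvas - 1e-6)
    ys = np.clip(cy + radii * np.sin(angles), 0, canvas - 1e-6)
    return list(zip(xs.tolist(), ys.tolist()))


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling oracle."""
    H, W = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    labels = np.zeros((H, W), dtype=int)
    cur = 0
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not labels[r, c]:
                cur += 1
                stack = [(r, c)]
                labels[r, c] = cur
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and not labels[ny, nx]:
                            labels[ny, nx] = cur
                            stack.append((ny, nx))
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two labelings agree up to a bijective renumbering."""
    if (a > 0).sum() != (b > 0).sum() or ((a > 0) != (b > 0)).any():
        return False
    pairs = set(zip(a[a > 0].tolist(), b[a > 0].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
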
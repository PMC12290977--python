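import numpy as np
import pytest

import osmotopo as ot


def flood_fill_chi(grid: np.ndarray) -> int:
    """Independent components-minus-holes oracle by breadth-first search.

    Foreground components are 8-connected; holes are 4-connected
    background components that do not touch the image border.
    """
    grid = np.asarray(grid, dtype=bool)
    h, w = grid.shape

    def bfs(start, target, neigh, seen):
        stack = [start]
        seen[start] = True
        cells = [start]
        while stack:
            i, j = stack.pop()
            for di, dj in neigh:
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and not seen[ni, nj] and grid[ni, nj] == target:
                    seen[ni, nj] = True
                    stack.append((ni, nj))
                    cells.append((ni, nj))
        return cells

    n8 = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    n4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    seen = np.zeros_like(grid)
    components = 0
    for i in range(h):
        for j in range(w):
            if grid[i, j] and not seen[i, j]:
                components += 1
                bfs((i, j), True, n8, seen)

    seen_bg = np.zeros_like(grid)
    holes = 0
    for i in range(h):
        for j in range(w):
            if not grid[i, j] and not seen_bg[i, j]:
                cells = bfs((i, j), False, n4, seen_bg)
                touches_border = any(
                    a == 0 or a == h - 1 or b == 0 or b == w - 1 for a, b in cells
                )
                if not touches_border:
                    holes += 1
    return components - holes


@pytest.fixture(scope="session")
def double_peak_config():
    """Imaging conditions for the double-peak studies: near-equilibrium
    frames with the plateau at mid-gray so neither texture tail clips."""
    return ot.SimulationConfig(
        seed=0,
        boundary_value=0.5,
        t_samples=(0.0, 64800.0),
    )


@pytest.fixture(scope="session")
def double_peak_images(double_peak_config):
    return ot.generate_impregnation_images(double_peak_config)
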
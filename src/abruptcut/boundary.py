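"""Freeman chain-code boundary tracing.

Directions are numbered counter-clockwise on the pixel grid, with row
indices increasing downward:

    0 = E, 1 = NE, 2 = N, 3 = NW, 4 = W, 5 = SW, 6 = S, 7 = SE

The trace itself walks the boundary clockwise (in image coordinates) using
Moore-neighbor tracing with Jacob's stopping criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from ._errors import ChainIntegrityError, EmptyMaskError, ParameterError
from .maskprep import LesionMask

#: direction symbol -> (drow, dcol); numbering increases counter-clockwise.
DIRECTIONS: Tuple[Tuple[int, int], ...] = (
    (0, 1),    # 0 E
    (-1, 1),   # 1 NE
    (-1, 0),   # 2 N
    (-1, -1),  # 3 NW
    (0, -1),   # 4 W
    (1, -1),   # 5 SW
    (1, 0),    # 6 S
    (1, 1),    # 7 SE
)

_DELTA_TO_DIR = {d: i for i, d in enumerate(DIRECTIONS)}

# Moore neighborhood in clockwise screen order starting at N.
_CLOCKWISE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass(frozen=True)
class ChainCode:
    start: Tuple[int, int]
    moves: Tuple[int, ...]

    def __post_init__(self) -> None:
        if any(mv not in range(8) for mv in self.moves):
            raise ParameterError("chain moves must be direction symbols 0..7")

    def __len__(self) -> int:
        return len(self.moves)

    def to_text(self) -> str:
        r, c = self.start
        return f"{r} {c} : " + " ".join(str(m) for m in self.moves)

    @classmethod
    def from_text(cls, text: str) -> "ChainCode":
        head, _, tail = text.partition(":")
        r, c = (int(t) for t in head.split())
        moves = tuple(int(t) for t in tail.split())
        return cls((r, c), moves)


@dataclass(frozen=True)
class BoundaryPath:
    """Ordered cyclic list of boundary pixels as (row, col)."""

    points: Tuple[Tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, i: int) -> Tuple[int, int]:
        return self.points[i]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=np.float64)

    def as_xy(self) -> np.ndarray:
        """(x, y) = (col, row) coordinate pairs."""
        arr = self.as_array()
        return arr[:, ::-1].copy()


@dataclass(frozen=True)
class CentroidPoint:
    """Foreground center of mass in (x, y) = (col, row) coordinates."""

    x: float
    y: float

    def as_xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def find_start_pixel(m: LesionMask) -> Tuple[int, int]:
    """Topmost foreground pixel; ties broken by smallest column."""
    rows, cols = np.nonzero(m.bits)
    if rows.size == 0:
        raise EmptyMaskError("cannot find start pixel of an empty mask")
    top = rows.min()
    left = cols[rows == top].min()
    return int(top), int(left)


def _is_fg(bits: np.ndarray, r: int, c: int) -> bool:
    return 0 <= r < bits.shape[0] and 0 <= c < bits.shape[1] and bits[r, c]


def trace_chain_code(m: LesionMask, start: Tuple[int, int] | None = None) -> ChainCode:
    """Clockwise Moore-neighbor boundary trace from the topmost-leftmost pixel.

    Stops when the walk re-enters the start pixel and is about to repeat
    its first move (Jacob's stopping criterion), which handles
    one-pixel-wide necks correctly.
    """
    bits = m.bits
    if start is None:
        start = find_start_pixel(m)
    sr, sc = start
    if not _is_fg(bits, sr, sc):
        raise ParameterError(f"start pixel {start} is not foreground")
    neighbors = [(sr + dr, sc + dc) for dr, dc in _CLOCKWISE]
    if all(not _is_fg(bits, r, c) for r, c in neighbors):
        return ChainCode(start, ())  # isolated pixel

    def _advance(cur, back):
        """Next boundary pixel clockwise and the new backtrack position."""
        cr, cc = cur
        k0 = _CLOCKWISE.index((back[0] - cr, back[1] - cc))
        for j in range(1, 9):
            dr, dc = _CLOCKWISE[(k0 + j) % 8]
            cand = (cr + dr, cc + dc)
            if _is_fg(bits, *cand):
                return cand, back
            back = cand
        raise AssertionError("unreachable: pixel has a foreground neighbor")

    # Initial backtrack is the pixel above the start (background, since the
    # start pixel is on the topmost foreground row). Terminate when the
    # walk re-enters the start pixel and is about to repeat its first move.
    path: List[Tuple[int, int]] = [start]
    current, backtrack = start, (sr - 1, sc)
    max_steps = 4 * (bits.size + 1)
    for _ in range(max_steps):
        nxt, backtrack = _advance(current, backtrack)
        if nxt == start and len(path) > 1:
            peek, _ = _advance(start, backtrack)
            if peek == path[1]:
                break
        path.append(nxt)
        current = nxt
    else:  # pragma: no cover - defensive
        raise ChainIntegrityError("boundary trace failed to terminate")

    moves = []
    for a, b in zip(path, path[1:] + [path[0]]):
        moves.append(_DELTA_TO_DIR[(b[0] - a[0], b[1] - a[1])])
    return ChainCode(start, tuple(moves))


def chain_to_path(c: ChainCode) -> BoundaryPath:
    """Expand a chain code to its pixel path; verifies closure."""
    if not c.moves:
        return BoundaryPath((c.start,))
    r, col = c.start
    pts = [(r, col)]
    for mv in c.moves:
        dr, dc = DIRECTIONS[mv]
        r, col = r + dr, col + dc
        pts.append((r, col))
    if pts[-1] != c.start:
        raise ChainIntegrityError(
            f"chain does not close: ends at {pts[-1]}, started at {c.start}"
        )
    return BoundaryPath(tuple(pts[:-1]))


def trace_boundary(m: LesionMask) -> BoundaryPath:
    """Convenience: trace and expand in one call."""
    return chain_to_path(trace_chain_code(m))


def centroid(m: LesionMask) -> CentroidPoint:
    """Arithmetic mean of foreground pixel coordinates."""
    rows, cols = np.nonzero(m.bits)
    if rows.size == 0:
        raise EmptyMaskError("centroid of an empty mask")
    return CentroidPoint(x=float(cols.mean()), y=float(rows.mean()))


def step_along(path: Sequence, i: int, k: int) -> int:
    """Index ``k`` boundary steps further along the cyclic path."""
    if k < 1:
        raise ParameterError(f"step count must be >= 1, got {k}")
    return (i + k) % len(path)
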
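"""DIA precursor isolation-window schemes.

A scheme partitions a precursor range into contiguous fixed-width core
windows; acquisition may extend each window (except the first) by a left
overlap, but precursor-to-window assignment always uses the half-open cores
so every m/z maps to exactly one window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class WindowScheme:
    windows: tuple[tuple[float, float], ...]
    nominal_width: float
    left_overlap: float
    range_start: float
    range_end: float

    def __len__(self) -> int:
        return len(self.windows)

    def core(self, index: int) -> tuple[float, float]:
        """Half-open non-overlapped core [start, end) of a 1-based window."""
        if not 1 <= index <= len(self.windows):
            raise IndexError(f"window index {index} out of range")
        return (
            self.range_start + (index - 1) * self.nominal_width,
            self.range_start + index * self.nominal_width,
        )


def make_window_scheme(
    range_start: float,
    range_end: float,
    width: float,
    left_overlap: float = 1.0,
) -> WindowScheme:
    """Build a fixed-width scheme; the first window has no left overlap."""
    if range_end <= range_start:
        raise ValueError(f"range_end must exceed range_start, got "
                         f"[{range_start}, {range_end}]")
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    span = range_end - range_start
    n = span / width
    if abs(n - round(n)) > 1e-9:
        nearest = range_start + round(n) * width
        raise ValueError(
            f"range span {span} is not divisible by width {width}; "
            f"nearest valid range_end is {nearest:g}"
        )
    n = round(n)
    windows = []
    for i in range(1, n + 1):
        start = range_start + (i - 1) * width
        if i > 1:
            start -= left_overlap
        windows.append((start, range_start + i * width))
    return WindowScheme(
        windows=tuple(windows),
        nominal_width=width,
        left_overlap=left_overlap,
        range_start=range_start,
        range_end=range_end,
    )


def assign_precursor_window(mz: float, scheme: WindowScheme) -> int | None:
    """1-based index of the core window containing mz, or None if out of
    range. Cores are half-open on the right."""
    if not scheme.range_start <= mz < scheme.range_end:
        return None
    idx = 1 + math.floor((mz - scheme.range_start) / scheme.nominal_width)
    return min(idx, len(scheme.windows))


def write_window_file(scheme: WindowScheme, path: str | Path) -> None:
    """Two-column swaths.txt dialect (tab-separated start/end per line)."""
    lines = [f"{s:g}\t{e:g}" for s, e in scheme.windows]
    Path(path).write_text("\n".join(lines) + "\n")


def read_window_file(path: str | Path) -> WindowScheme:
    """Reconstruct a scheme from a swaths.txt file written by
    :func:`write_window_file`."""
    windows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        windows.append((float(parts[0]), float(parts[1])))
    if not windows:
        raise ValueError(f"{path}: no windows found")
    range_start = windows[0][0]
    range_end = windows[-1][1]
    width = windows[0][1] - windows[0][0]
    overlap = (windows[0][1] - windows[1][0]) if len(windows) > 1 else 0.0
    return WindowScheme(
        windows=tuple(windows),
        nominal_width=width,
        left_overlap=overlap,
        range_start=range_start,
        range_end=range_end,
    )
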
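"""Independent brute-force oracles used only by the tests.

Every function here evaluates region predicates pixel by pixel with plain
Python loops, deliberately sharing no code with the library's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np


def oracle_subqf_regions(
    subqf: np.ndarray,
    ischium: np.ndarray,
    landmark_row: int,
    spacing_mm: tuple[float, float],
    margin_mm: float = 5.0,
    band_mm: float = 10.0,
) -> tuple[set, set]:
    """Enumerate (under, surrounding) pixel sets by direct predicate checks."""
    sp_r, sp_c = spacing_mm
    n_rows, n_cols = subqf.shape

    foot_cols = []
    for r in range(n_rows):
        for c in range(n_cols):
            if ischium[r, c] and (landmark_row - r) * sp_r <= band_mm:
                foot_cols.append(c)
    assert foot_cols, "oracle: empty ischium footprint"
    lo = min(foot_cols) * sp_c - margin_mm
    hi = max(foot_cols) * sp_c + margin_mm

    under, surrounding = set(), set()
    for r in range(n_rows):
        for c in range(n_cols):
            if not subqf[r, c]:
                continue
            if (landmark_row - r) * sp_r > band_mm:
                continue
            if lo <= c * sp_c <= hi:
                under.add((r, c))
            else:
                surrounding.add((r, c))
    return under, surrounding


def oracle_imat_regions(
    subqf: np.ndarray,
    gluteus: np.ndarray,
    landmark_col: int,
    spacing_mm: tuple[float, float],
) -> tuple[set, set]:
    """Enumerate (ref_adipose, gluteus) pixel sets by direct predicate checks."""
    sp_r, sp_c = spacing_mm
    n_rows, n_cols = subqf.shape
    glut = {(r, c) for r in range(n_rows) for c in range(n_cols) if gluteus[r, c]}

    ref = set()
    for r in range(n_rows):
        for c in range(n_cols):
            if not subqf[r, c]:
                continue
            if c * sp_c <= landmark_col * sp_c:
                continue
            col_glut_rows = [rr for rr in range(n_rows) if gluteus[rr, c]]
            if not col_glut_rows:
                continue
            if r > max(col_glut_rows):
                ref.add((r, c))
    return ref, glut


def oracle_effect_size(a, b) -> float:
    """Pooled-SD standardized mean difference, written out longhand."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp = (((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)) ** 0.5
    return (ma - mb) / sp


def region_set(region) -> set:
    """Coordinate set of a RegionIntensities for comparison with oracles."""
    return {tuple(rc) for rc in np.asarray(region.pixel_coords)}
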
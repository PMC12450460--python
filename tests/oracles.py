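"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct definition
available, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# grayscale opening with a spherical-cap (ball) structuring element


def ball_heights(radius: int) -> dict[tuple[int, int], float]:
    """Offset -> cap height sqrt(r^2 - d^2) over the disc d <= r."""
    out = {}
    for oy in range(-radius, radius + 1):
        for ox in range(-radius, radius + 1):
            d2 = ox * ox + oy * oy
            if d2 <= radius * radius:
                out[(oy, ox)] = math.sqrt(radius * radius - d2)
    return out


def brute_opening(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Erosion then dilation with the ball element, reflective borders.

    Implemented as explicit shift-and-min / shift-and-max over the
    padded array, then clamped into [0, input] (the defined output
    range of the background surface).
    """
    heights = ball_heights(radius)
    h, w = pixels.shape
    padded = np.pad(pixels, radius, mode="symmetric")
    eroded = np.full_like(pixels, np.inf)
    for (oy, ox), hv in heights.items():
        window = padded[radius + oy : radius + oy + h, radius + ox : radius + ox + w]
        eroded = np.minimum(eroded, window - hv)
    padded_e = np.pad(eroded, radius, mode="symmetric")
    dilated = np.full_like(pixels, -np.inf)
    for (oy, ox), hv in heights.items():
        window = padded_e[radius + oy : radius + oy + h, radius + ox : radius + ox + w]
        dilated = np.maximum(dilated, window + hv)
    return np.maximum(np.minimum(dilated, pixels), 0.0)


# ---------------------------------------------------------------------------
# dense 2-D Gaussian convolution (for small images)


def dense_gaussian(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Direct convolution with a truncated normalized Gaussian kernel.

    Matches the default 4-sigma truncation of separable implementations.
    """
    radius = int(4 * sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    h, w = pixels.shape
    padded = np.pad(pixels, radius, mode="symmetric")
    out = np.zeros_like(pixels, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum by full enumeration


def enumerate_rank_sum_p(x, y, alternative: str = "two-sided") -> float:
    """Exact p for tie-free samples by enumerating every rank split."""
    pooled = sorted(x) + sorted(y)
    assert len(set(x) | set(y)) == len(x) + len(y), "oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    center = n * m / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if alternative == "less":
            count += u <= u_obs
        elif alternative == "greater":
            count += u >= u_obs
        else:
            count += abs(u - center) >= abs(u_obs - center) - 1e-12
    return count / total


# ---------------------------------------------------------------------------
# peptide mass from elemental composition (IUPAC standard atomic weights)

_ATOMIC = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# residue (amino acid minus one water) CHNOS counts
_RESIDUE_CHNOS = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}


def elemental_peptide_mass(sequence: str) -> float:
    """Average peptide mass summed from per-residue CHNOS composition."""
    c = h = n = o = s = 0
    for aa in sequence:
        dc, dh, dn, do, ds = _RESIDUE_CHNOS[aa]
        c, h, n, o, s = c + dc, h + dh, n + dn, o + do, s + ds
    h += 2  # one water per chain
    o += 1
    return (
        c * _ATOMIC["C"] + h * _ATOMIC["H"] + n * _ATOMIC["N"]
        + o * _ATOMIC["O"] + s * _ATOMIC["S"]
    )
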
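"""Brute-force oracles used by the acceptance script (independent of the package)."""

import numpy as np

from chronoplex import focusproj as fp


def brute_force_entropy(plane, width):
    """Per-pixel nested-loop histogram-entropy oracle."""
    q = fp.quantize_plane(plane)
    before = width // 2 - (1 if width % 2 == 0 else 0)
    after = width // 2
    pad = np.pad(q, ((before, after), (before, after)), mode="symmetric")
    out = np.zeros(plane.shape)
    n = width * width
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            win = pad[i:i + width, j:j + width].ravel()
            counts = np.bincount(win, minlength=256).astype(float)
            p = counts[counts > 0] / n
            out[i, j] = -(p * np.log2(p)).sum()
    return out


def brute_force_distance(point, poly):
    """Nested-loop point-to-segment distance oracle."""
    best = np.inf
    p = np.asarray(point, float)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else np.clip((p - a) @ ab / denom, 0.0, 1.0)
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best
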
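"""Independent brute-force reference for the detection predicates.

Deliberately written as plain per-pixel loops with numpy's stock statistics
(np.median, np.corrcoef) so it shares no code path with the vectorized
implementation it cross-checks.
"""

import numpy as np


def brute_force_detect(projection, params):
    """Evaluate every interior pixel against the three acceptance predicates.

    Returns (candidates, detections) as lists of (row, col, peak, value)
    tuples, ordered by descending peak (ties by row, col) like the library.
    """
    proj = np.asarray(projection, dtype=float)
    h, w = proj.shape
    r = params.patch_radius
    factor = 1.0 + params.background_threshold_pct / 100.0
    d = np.arange(-r, r + 1)
    rr, cc = np.meshgrid(d, d, indexing="ij")
    template = np.exp(-(rr**2 + cc**2) / (2.0 * params.template_sigma**2))

    candidates = []
    for row in range(r, h - r):
        for col in range(r, w - r):
            v = proj[row, col]
            is_max = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nb = proj[row + dr, col + dc]
                    # strict against lexicographically preceding neighbors,
                    # weak against the rest (plateau tie-break)
                    if (dr, dc) < (0, 0):
                        if not v > nb:
                            is_max = False
                    else:
                        if not v >= nb:
                            is_max = False
            if not is_max:
                continue
            perim = [
                proj[row + dr, col + dc]
                for dr in range(-r, r + 1)
                for dc in range(-r, r + 1)
                if max(abs(dr), abs(dc)) == r
            ]
            bg = float(np.median(perim))
            if v >= factor * bg:
                candidates.append((row, col, float(v), bg))

    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    detections = []
    for row, col, peak, bg in candidates:
        patch = proj[row - r : row + r + 1, col - r : col + r + 1]
        if patch.std() == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(patch.ravel(), template.ravel())[0, 1])
        if corr > params.correlation_min:
            detections.append((row, col, peak, corr))
    return candidates, detections
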
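"""Exhaustive-search oracle for collinear chaining, independent of the DP.

Enumerates every monotone chain by depth-first extension over anchors
sorted by rank_a and returns the maximum chain size.  Exponential, so
only usable on tiny instances (<= ~12 anchors)."""


def _extend(points, i, orientation, max_gap):
    best = 1
    ra, rb = points[i]
    for j in range(len(points)):
        da = points[j][0] - ra
        if not 0 < da <= max_gap:
            continue
        db = points[j][1] - rb if orientation == "parallel" else rb - points[j][1]
        if not 0 < db <= max_gap:
            continue
        best = max(best, 1 + _extend(points, j, orientation, max_gap))
    return best


def exhaustive_best_chain_size(points, max_gap):
    """Max monotone chain size over both orientations (brute force)."""
    if not points:
        return 0
    return max(
        _extend(points, i, orientation, max_gap)
        for i in range(len(points))
        for orientation in ("parallel", "antiparallel")
    )
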
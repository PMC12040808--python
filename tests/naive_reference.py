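"""Independent brute-force reference for the trimming pipeline.

Deliberately written as plain Python loops over (time, pressure) tuples,
with no shared code or vectorization, so it can serve as an oracle for the
production implementation.  Conventions mirror the documented filter
contract: inclusive 50 mbar activity threshold, inclusive 2x gap factor,
move_max removes the peak plus the following points, smoothing is a
centred shrink-at-edges moving mean.
"""

from __future__ import annotations


def naive_preprocess(times, pressures, cfg, apply_smoothing=True):
    """Full (i)->(v) + move_max + smoothing pipeline, naive edition.

    ``cfg`` is any object with the configuration attributes.  Returns a
    list of (times, pressures) tuples of plain Python lists, one per
    retained cycle.
    """
    pts = [(float(t), float(p)) for t, p in zip(times, pressures)]

    # (i) min-pressure floor
    pts = [tp for tp in pts if tp[1] >= cfg.min_pressure]

    # (ii) segmentation
    cycles = naive_segment(pts, cfg)

    # (iii) short cycles
    cycles = [c for c in cycles if len(c) >= cfg.len_cycles]

    # (iv) inactive cycles (inclusive threshold)
    cycles = [c for c in cycles if c[0][1] - c[-1][1] >= cfg.pressure_drop_min]

    out = []
    for c in cycles:
        # (v) truncate at the first oversized gap (inclusive 2x bound)
        kept = [c[0]]
        for tp in c[1:]:
            if tp[0] - kept[-1][0] <= 2.0 * cfg.sample_interval:
                kept.append(tp)
        c = kept
        # move_max: drop the peak and the move_max points after it
        if cfg.move_max > 0:
            c = c[cfg.move_max + 1:]
        if len(c) < 2:
            continue
        out.append(c)

    result = []
    for c in out:
        ts = [tp[0] for tp in c]
        ps = [tp[1] for tp in c]
        if apply_smoothing and cfg.average > 1:
            ps = naive_smooth(ps, cfg.average)
        result.append((ts, ps))
    return result


def naive_segment(pts, cfg):
    """Peak-to-threshold/minimum cycles between re-pressurization rises."""
    n = len(pts)
    if n == 0:
        return []
    p = [tp[1] for tp in pts]

    # maximal strictly-increasing runs with total rise >= refill_threshold
    runs = []
    i = 0
    while i < n - 1:
        if p[i + 1] > p[i]:
            j = i
            while j < n - 1 and p[j + 1] > p[j]:
                j += 1
            if p[j] - p[i] >= cfg.refill_threshold:
                runs.append((i, j))
            i = j
        else:
            i += 1

    blocks = []
    prev_top = 0
    for start, top in runs:
        blocks.append((prev_top, start))
        prev_top = top
    blocks.append((prev_top, n - 1))

    cycles = []
    for a, b in blocks:
        if b - a + 1 < 2:
            continue
        peak = a
        for k in range(a, b + 1):
            if p[k] > p[peak]:
                peak = k
        if b - peak + 1 < 2:
            continue
        stop = p[peak] - cfg.delta_p_cycle * 1000.0
        end = b
        for k in range(peak, b + 1):
            if p[k] <= stop:
                end = k
                break
        if end - peak + 1 < 2:
            continue
        cycles.append(pts[peak:end + 1])
    return cycles


def naive_smooth(values, window):
    """Centred moving mean, window shrinking at the edges."""
    n = len(values)
    # even windows put their extra element on the left
    half_left = window // 2
    half_right = (window - 1) // 2
    out = []
    for i in range(n):
        lo = max(0, i - half_left)
        hi = min(n, i + half_right + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out
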
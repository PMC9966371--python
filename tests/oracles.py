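"""Independent brute-force oracles used to cross-check the pipeline.

These are deliberately naive pure-Python scans, kept separate from the
package so they share no code path with the implementations they check.
"""

from __future__ import annotations

import math


def brute_first_crossing(times, values, threshold, direction,
                         anchor=0.0, debounce=1):
    """First time beginning a run of >= debounce samples satisfying the
    threshold condition, scanning sample by sample from ``anchor``."""
    run = 0
    run_start = None
    for t, v in zip(times, values):
        if t < anchor:
            continue
        if math.isnan(v):
            ok = False
        elif direction == "below":
            ok = v < threshold
        else:
            ok = v >= threshold
        if ok:
            if run == 0:
                run_start = t
            run += 1
            if run >= debounce:
                return run_start
        else:
            run = 0
    return None


def brute_dwell_time(times, values, threshold, nominal_dt):
    """Sum of local inter-sample intervals over sub-threshold samples;
    the last sample contributes the nominal dt."""
    total = 0.0
    n = len(times)
    for i in range(n):
        v = values[i]
        if math.isnan(v) or not v < threshold:
            continue
        total += (times[i + 1] - times[i]) if i < n - 1 else nominal_dt
    return total


def brute_mask_intervals(times, values):
    """Run-length scan of mask == 0."""
    intervals = []
    dm = None
    for t, v in zip(times, values):
        if v == 0 and dm is None:
            dm = t
        elif v == 1 and dm is not None:
            intervals.append((dm, t))
            dm = None
    if dm is not None:
        intervals.append((dm, None))
    return intervals
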
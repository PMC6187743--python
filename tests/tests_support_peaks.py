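"""Shared independent oracle: brute-force peak counting."""

import numpy as np


def brute_force_peak_count(profile, prominence_frac):
    """Independent O(n^2) local-maxima scan with prominence measured
    against the higher of the two flanking minima (walking outward until a
    strictly higher sample or the signal edge)."""
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    rng = profile.max() - profile.min()
    if n < 3 or rng == 0:
        return 0
    count = 0
    i = 1
    while i < n - 1:
        # plateau-aware local maximum detection
        j = i
        while j < n - 1 and profile[j + 1] == profile[j]:
            j += 1
        if profile[i - 1] < profile[i] and j < n - 1 and profile[j + 1] < profile[j]:
            h = profile[i]
            left = profile[:i][::-1]
            lmin = h
            for v in left:
                if v > h:
                    break
                lmin = min(lmin, v)
            rmin = h
            for v in profile[j + 1:]:
                if v > h:
                    break
                rmin = min(rmin, v)
            if h - max(lmin, rmin) > prominence_frac * rng:
                count += 1
            i = j + 1
        else:
            i += 1
    return count
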
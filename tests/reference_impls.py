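"""Independent brute-force reference implementations used as oracles.

These are deliberately simple, list-based re-statements of the rules, kept
free of any code shared with the package so that equivalence tests are
meaningful.
"""

from __future__ import annotations


def reference_threshold_labels(values, thresholds):
    """A frame's label is the number of thresholds strictly below its value
    (a value equal to a threshold belongs to the class below it)."""
    return [sum(1 for t in thresholds if t < v) for v in values]


def reference_merge_short_runs(labels, min_len):
    """Runs shorter than min_len merge into the neighbour with the longer
    adjacent run; ties go to the earlier neighbour; repeat until stable."""
    labels = list(labels)
    while True:
        runs = []
        for lab in labels:
            if runs and runs[-1][0] == lab:
                runs[-1][1] += 1
            else:
                runs.append([lab, 1])
        if len(runs) <= 1:
            break
        short = None
        for i, (lab, ln) in enumerate(runs):
            if ln < min_len:
                short = i
                break
        if short is None:
            break
        left = runs[short - 1] if short > 0 else None
        right = runs[short + 1] if short < len(runs) - 1 else None
        if left is not None and (right is None or left[1] >= right[1]):
            runs[short][0] = left[0]
        else:
            runs[short][0] = right[0]
        labels = []
        for lab, ln in runs:
            labels.extend([lab] * ln)
    return labels


def reference_fluctuation_filter(nr_r_sequence, thresh5, thresh1):
    """Brute-force restatement of the spontaneous-fluctuation correction.

    Input: list of (state, duration) with state in {"non_rotated",
    "rotated"}.  Output: the filtered, merged list of (state, duration).
    """
    seq = [[s, d] for s, d in nr_r_sequence]
    nr_positions = [i for i, (s, _) in enumerate(seq) if s == "non_rotated"]
    # rule 1: first consecutive pair of sub-5%-tile non-rotated dwells stops
    # the translation count; they and all later non-rotated dwells become
    # rotated
    stop = None
    for j in range(len(nr_positions) - 1):
        if (seq[nr_positions[j]][1] < thresh5
                and seq[nr_positions[j + 1]][1] < thresh5):
            stop = j
            break
    if stop is not None:
        for i in nr_positions[stop:]:
            seq[i][0] = "rotated"
        nr_positions = nr_positions[:stop]
    # rule 2: remaining sub-1%-tile non-rotated dwells are removed (become
    # rotated time)
    for i in nr_positions:
        if seq[i][1] < thresh1:
            seq[i][0] = "rotated"
    # merge adjacent equal states
    merged = []
    for s, d in seq:
        if merged and merged[-1][0] == s:
            merged[-1][1] += d
        else:
            merged.append([s, d])
    return [(s, d) for s, d in merged]
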
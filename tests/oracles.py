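"""Independent brute-force oracles used by unit and acceptance tests."""

from alushare import TsdCall
from alushare.inspection import estimate_atail_end


def brute_force_tsd(seq, alu_span, min_len=6, max_len=25, max_mismatch=1, slack=5,
                    tail_backtrack=16):
    """Enumerate every (right-copy start, length) pair and apply the
    documented tie rules: longest first, then fewest mismatches, then the
    leftmost right-copy start."""
    start, end = alu_span
    atail = estimate_atail_end(seq, end)
    candidates = []
    for s in range(max(end, atail - slack - tail_backtrack),
                   min(len(seq), atail + slack + 1)):
        for length in range(min_len, max_len + 1):
            if length > start or s + length > len(seq):
                continue
            left = seq[start - length : start]
            right = seq[s : s + length]
            mism = sum(a != b for a, b in zip(left, right))
            if mism <= max_mismatch:
                candidates.append((-length, mism, s, left))
    if not candidates:
        return None
    neg_length, mism, s, word = min(candidates)
    length = -neg_length
    return TsdCall((start - length, start), (s, s + length), word, mism)
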
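"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written as plain Python loops over the
mathematical definitions, sharing no code path with the package.
"""

from __future__ import annotations

import math


def rms_loop(x) -> float:
    s = 0.0
    for v in x:
        s += float(v) * float(v)
    return math.sqrt(s / len(x))


def variance_loop(x) -> float:
    n = len(x)
    mean = sum(float(v) for v in x) / n
    return sum((float(v) - mean) ** 2 for v in x) / (n - 1)


def zero_crossings_loop(x, eps: float = 0.0) -> int:
    count = 0
    for i in range(len(x) - 1):
        if -float(x[i]) * float(x[i + 1]) > eps:
            count += 1
    return count


def waveform_length_loop(x) -> float:
    return sum(abs(float(x[i + 1]) - float(x[i])) for i in range(len(x) - 1))


def sample_entropy_loop(x, m: int, r: float) -> float:
    """SampEn(m, r*SD) by exhaustive O(N^2) template comparison; templates of
    both lengths taken from the first N-m positions, self-matches excluded."""
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    tol = r * sd

    def count_matches(length: int) -> int:
        total = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                dist = max(
                    abs(float(x[i + k]) - float(x[j + k])) for k in range(length)
                )
                if dist <= tol:
                    total += 1
        return total

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0 or a == 0:
        return math.inf
    return -math.log(a / b)


def mean_frequency_loop(freqs, power) -> float:
    num = 0.0
    den = 0.0
    for f, p in zip(freqs, power):
        num += float(f) * float(p)
        den += float(p)
    return num / den


def median_frequency_loop(freqs, power) -> float:
    total = sum(float(p) for p in power)
    cum = 0.0
    for f, p in zip(freqs, power):
        cum += float(p)
        if cum >= total / 2.0:
            return float(f)
    return float(freqs[-1])


def window_count_enum(T: int, L: int, H: int) -> int:
    """Count window placements by walking start positions."""
    count = 0
    s = 0
    while s + L <= T:
        count += 1
        s += H
    return count


def two_stage_mean(rows) -> float:
    """Mean over subjects of the per-subject mean accuracy.

    ``rows`` is an iterable of (subject, accuracy) pairs.
    """
    by_subject: dict = {}
    for subject, acc in rows:
        by_subject.setdefault(subject, []).append(acc)
    subject_means = [sum(v) / len(v) for v in by_subject.values()]
    return sum(subject_means) / len(subject_means)
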
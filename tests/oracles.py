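"""Independent brute-force reference implementations used only by tests.

Everything here is written in the most literal form possible (plain loops,
fnmatch wildcards, textbook formulas) so it shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import math
from fnmatch import fnmatchcase


def dict_relative_frequency(tokens: list[str], patterns: list[str]) -> float:
    """Matched-token count over total tokens, wildcards via fnmatch."""
    if not tokens:
        return 0.0
    matched = 0
    for token in tokens:
        for pattern in patterns:
            if fnmatchcase(token, pattern):
                matched += 1
                break
    return matched / len(tokens)


def topic_loading(tokens: list[str], entries: dict[tuple[int, str], float],
                  topic_id: int) -> float:
    """Sum over in-vocabulary tokens of freq(w) * p(topic_id | w)."""
    vocab = {w for _, w in entries}
    in_vocab = [t for t in tokens if t in vocab]
    if not in_vocab:
        return 0.0
    loading = 0.0
    for token in in_vocab:
        total = sum(wt for (tid, w), wt in entries.items() if w == token)
        weight = entries.get((topic_id, token), 0.0)
        loading += (1.0 / len(in_vocab)) * (weight / total)
    return loading


def lexicon_score(tokens: list[str], weights: dict[str, float],
                  intercept: float = 0.0) -> float:
    if not tokens:
        return intercept
    return intercept + sum(weights.get(t, 0.0) for t in tokens) / len(tokens)


def paired_t(true_vals, null_vals) -> tuple[float, float]:
    """Textbook paired t; p from scipy's t CDF (the comparison target is
    the statistic; scipy.stats.ttest_rel is used separately as a full
    reference)."""
    from scipy.stats import t as tdist

    diffs = [a - b for a, b in zip(true_vals, null_vals)]
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, 2 * tdist.sf(abs(t), n - 1)


def cohens_dz(diffs) -> float:
    n = len(diffs)
    mean = sum(diffs) / n
    sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
    return mean / sd


def bh_step_up(p_values: list[float]) -> list[float]:
    """Literal step-up definition: adjusted(i) = min over j with
    p_j >= p_i of min(1, p_j * m / ascending-rank(j))."""
    m = len(p_values)
    ranked = sorted(range(m), key=lambda i: p_values[i])
    rank_of = {idx: r + 1 for r, idx in enumerate(ranked)}
    out = []
    for i in range(m):
        candidates = [
            min(1.0, p_values[j] * m / rank_of[j])
            for j in range(m)
            if p_values[j] >= p_values[i]
        ]
        out.append(min(candidates))
    return out


def auc_pairwise(scores, labels) -> float:
    """O(n^2) Mann-Whitney AUC with ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
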
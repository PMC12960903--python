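"""Fickett TESTCODE coding-potential statistic.

The classic statistic combines, for each base, a position parameter
(asymmetry of the base across the three codon positions) and a content
parameter (overall base fraction). Each parameter is converted to a
coding probability via the published lookup tables and the eight
probabilities are combined with the published weights. Scores range from
roughly 0.2 to 1.6; higher means more coding-like.

N bases are excluded from both position and composition counts.
"""

from __future__ import annotations

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_CUTS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_CUTS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

_BASES = "ACGT"


def _lookup(value: float, cuts: tuple[float, ...], probs: tuple[float, ...]) -> float:
    for cut, prob in zip(cuts, probs):
        if value >= cut:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE score of a nucleotide sequence (deterministic, N-insensitive)."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("fickett_score requires a sequence of length >= 2")

    pos_counts = {base: [0, 0, 0] for base in _BASES}
    comp_counts = dict.fromkeys(_BASES, 0)
    for i, base in enumerate(seq):
        if base in pos_counts:
            pos_counts[base][i % 3] += 1
            comp_counts[base] += 1

    total = sum(comp_counts.values())
    score = 0.0
    for base in _BASES:
        counts = pos_counts[base]
        position_param = max(counts) / (min(counts) + 1.0)
        score += _lookup(position_param, _POSITION_CUTS, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        content_param = comp_counts[base] / total if total else 0.0
        score += _lookup(content_param, _CONTENT_CUTS, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score
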
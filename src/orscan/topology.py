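"""Transmembrane topology and N-glycosylation sequon annotation.

OR proteins are rhodopsin-like GPCRs with seven transmembrane helices.
Topology here is predicted from Kyte-Doolittle window-averaged hydropathy
(window 19, cutoff 1.6): maximal runs of residues whose window mean
exceeds the cutoff become candidate segments, near-adjacent segments are
merged, and short remnants are dropped. The result annotates gene models
(``tm_count``, ``topology_ok`` for 6-8 helices) without changing their
functional status unless a strict mode is requested downstream.

N-glycosylation sites are canonical N-X-S/T sequons with X != P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_SEP = 3
MIN_SEGMENT_AA = 15
TM_OK_RANGE = (6, 8)


@dataclass
class TmProfile:
    hydropathy: np.ndarray
    segments: list[tuple[int, int]]

    @property
    def tm_count(self) -> int:
        return len(self.segments)

    @property
    def topology_ok(self) -> bool:
        return TM_OK_RANGE[0] <= self.tm_count <= TM_OK_RANGE[1]


def predict_tm(
    peptide: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    min_sep: int = DEFAULT_MIN_SEP,
) -> TmProfile:
    """Hydropathy-window transmembrane segment prediction.

    Each residue's score is the mean Kyte-Doolittle hydropathy over a
    centred window (truncated at the termini). Runs above ``threshold``
    become segments; segments separated by fewer than ``min_sep`` residues
    are merged, and segments shorter than 15 aa are dropped.
    """
    n = len(peptide)
    if n < window:
        raise ValueError(f"peptide of {n} aa shorter than window {window}")
    values = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in peptide])
    half = window // 2
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    starts = np.maximum(0, np.arange(n) - half)
    ends = np.minimum(n, np.arange(n) + half + 1)
    profile = (cumsum[ends] - cumsum[starts]) / (ends - starts)

    above = profile > threshold
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1

    merged: list[tuple[int, int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] < min_sep:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)
    merged = [s for s in merged if s[1] - s[0] >= MIN_SEGMENT_AA]
    return TmProfile(hydropathy=profile, segments=merged)


def find_sequons(peptide: str) -> list[int]:
    """0-based positions i of N-X-S/T sequons (X != P); overlaps reported."""
    if not peptide:
        raise ValueError("empty peptide")
    return [
        i
        for i in range(len(peptide) - 2)
        if peptide[i] == "N" and peptide[i + 1] != "P" and peptide[i + 2] in "ST"
    ]


def annotate_models(models, window: int = DEFAULT_WINDOW, threshold: float = DEFAULT_THRESHOLD) -> None:
    """Fill tm_count / topology_ok / sequons on gene models in place.

    Models whose peptide is shorter than the window get tm_count 0.
    """
    for m in models:
        if len(m.peptide) >= window:
            prof = predict_tm(m.peptide, window=window, threshold=threshold)
            m.tm_count = prof.tm_count
            m.topology_ok = prof.topology_ok
        else:
            m.tm_count = 0
            m.topology_ok = False
        m.sequons = find_sequons(m.peptide) if m.peptide else []
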
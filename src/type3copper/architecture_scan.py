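"""Sequence-only prediction of the domain architecture features that
separate the three subclasses: N-terminal signal peptide (secreted α and
membrane-bound γ), transmembrane segment (γ only) and cysteine-rich
region (γ).  All detectors are Kyte-Doolittle hydropathy / composition
heuristics with documented, configurable thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError
from .seqio import ProteinRecord

#: Kyte-Doolittle hydropathy index; X (unknown) contributes 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

Span = tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class ArchitectureParams:
    sp_search_len: int = 35
    sp_core_window: int = 8
    sp_core_min_hydropathy: float = 1.6
    sp_max_start: int = 12
    tm_window: int = 19
    tm_min_hydropathy: float = 1.6
    tm_merge_gap: int = 5
    cys_window: int = 30
    cys_min_count: int = 6

    def __post_init__(self):
        if min(self.sp_core_window, self.tm_window, self.cys_window) < 1:
            raise DataError("windows must be >= 1")


@dataclass(frozen=True)
class DomainArchitecture:
    signal_peptide: Optional[Span]
    tm_segments: tuple[Span, ...]
    cys_rich_regions: tuple[Span, ...]
    hydropathy_profile: dict[int, float] = field(default_factory=dict,
                                                 compare=False, repr=False)

    @property
    def has_sp(self) -> bool:
        return self.signal_peptide is not None

    @property
    def has_tm(self) -> bool:
        return len(self.tm_segments) > 0


def hydropathy(sequence: str, window: int) -> dict[int, float]:
    """Centered windowed mean hydropathy, position -> value.

    Positions whose window would overrun either end are absent.  The
    window must be odd and no longer than the sequence.
    """
    if window % 2 == 0:
        raise DataError("hydropathy window must be odd")
    if window > len(sequence):
        raise DataError("hydropathy window exceeds sequence length")
    values = np.array([KYTE_DOOLITTLE.get(ch, 0.0) for ch in sequence])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    half = window // 2
    return {i + half: float(means[i]) for i in range(len(means))}


def detect_signal_peptide(sequence: str,
                          params: ArchitectureParams = ArchitectureParams()
                          ) -> Optional[Span]:
    """First hydrophobic core window in the N-terminal search region.

    Present iff some ``sp_core_window`` consecutive residues starting at
    index <= ``sp_max_start`` (within the first ``sp_search_len``) have
    mean hydropathy >= the threshold; the predicted span runs from 0 to
    three residues past that window (approximate cleavage), capped at the
    search length.
    """
    w = params.sp_core_window
    if len(sequence) < w:
        return None
    region = sequence[:params.sp_search_len]
    values = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in region]
    last_start = min(params.sp_max_start, len(region) - w)
    for start in range(0, last_start + 1):
        if sum(values[start:start + w]) / w >= params.sp_core_min_hydropathy:
            end = min(start + w + 3, params.sp_search_len, len(sequence))
            return (0, end)
    return None


def detect_tm_segments(sequence: str,
                       params: ArchitectureParams = ArchitectureParams(),
                       exclude: Optional[Span] = None) -> list[Span]:
    """Maximal runs of hydrophobic windowed positions, TM-length or more.

    A position qualifies when its centered ``tm_window`` mean hydropathy
    reaches the threshold and it lies outside ``exclude`` (the signal
    peptide).  Qualifying runs shorter than ``tm_window`` are dropped;
    surviving runs separated by fewer than ``tm_merge_gap`` positions are
    merged.
    """
    if len(sequence) < params.tm_window:
        return []
    profile = hydropathy(sequence, params.tm_window)
    ex_lo, ex_hi = exclude if exclude is not None else (0, 0)
    qualifying = sorted(
        i for i, v in profile.items()
        if v >= params.tm_min_hydropathy and not (ex_lo <= i < ex_hi))
    runs: list[list[int]] = []
    for pos in qualifying:
        if runs and pos == runs[-1][1]:
            runs[-1][1] = pos + 1
        else:
            runs.append([pos, pos + 1])
    spans = [(a, b) for a, b in runs if b - a >= params.tm_window]
    merged: list[Span] = []
    for span in spans:
        if merged and span[0] - merged[-1][1] < params.tm_merge_gap:
            merged[-1] = (merged[-1][0], span[1])
        else:
            merged.append(span)
    return merged


def detect_cys_rich(sequence: str,
                    params: ArchitectureParams = ArchitectureParams()
                    ) -> list[Span]:
    """Merged spans of windows with at least ``cys_min_count`` cysteines."""
    w = params.cys_window
    if len(sequence) < w:
        return []
    is_cys = np.array([ch == "C" for ch in sequence], dtype=int)
    counts = np.convolve(is_cys, np.ones(w, dtype=int), mode="valid")
    merged: list[list[int]] = []
    for start in range(len(counts)):
        if counts[start] < params.cys_min_count:
            continue
        end = start + w
        if merged and start <= merged[-1][1]:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def build_architecture(record: ProteinRecord,
                       params: ArchitectureParams = ArchitectureParams()
                       ) -> DomainArchitecture:
    """Compose the three detectors; TM detection excludes the SP span."""
    sp = detect_signal_peptide(record.sequence, params)
    tm = detect_tm_segments(record.sequence, params, exclude=sp)
    cys = detect_cys_rich(record.sequence, params)
    try:
        profile = hydropathy(record.sequence, params.tm_window)
    except DataError:
        profile = {}
    return DomainArchitecture(signal_peptide=sp,
                              tm_segments=tuple(tm),
                              cys_rich_regions=tuple(cys),
                              hydropathy_profile=profile)
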
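"""G-quadruplex detection and quantification.

Three independent routes to calling G-quadruplexes (G4s) in RNA:

1. **Sequence motif**: four WGGA tracts (W = A or U) separated by short
   linkers, found with the lookahead regular expression
   ``(?=([AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA(.{0,6})[AU]GGA))`` so that
   overlapping elements at distinct start offsets are counted separately.
2. **Predicted structure**: per-nucleotide ``+`` annotations from an external
   folding engine run on 80-nt windows slid 20 nt at a time; a nucleotide
   participates in a quadruplex if any covering window marks it ``+``.
3. **Experimental RT stops**: reverse transcriptase stalls at folded G4s in
   K+ but not Li+ conditions; positions whose K+ stop count is at least
   ``ratio_min`` times the Li+ count define a G4 in the 60 nt upstream.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RnaSequence",
    "G4Match",
    "StructureWindow",
    "G4Mask",
    "ExperimentalG4",
    "wgga_pattern",
    "scan_wgga",
    "wgga_density",
    "make_windows",
    "quadruplex_mask",
    "quadruplex_g_density",
    "call_rt_stop_g4",
    "experimental_overlap_density",
]

_VALID_RESIDUES = frozenset("ACGUN")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence; DNA input is normalized (T -> U, uppercase).

    Parameters
    ----------
    id : sequence identifier
    residues : string over {A, C, G, U, N} after normalization
    region : optional region label, e.g. "5UTR", "CDS", "3UTR"
    """

    id: str
    residues: str
    region: str | None = None

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        if not norm:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(norm) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: invalid residues {sorted(bad)}; "
                "expected A/C/G/T/U/N"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class G4Match:
    """One WGGA-element match. ``span`` starts and ends with a WGGA tract."""

    seq_id: str
    start: int
    end: int
    span: str
    linkers: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.end - self.start != 16 + sum(self.linkers):
            raise ValueError("span length inconsistent with linkers")


@dataclass(frozen=True)
class StructureWindow:
    """Folded-structure annotation for one window of a sequence.

    ``structure`` is a string over ``. ( ) +`` of the window's length;
    ``+`` marks a nucleotide predicted to participate in a quadruplex.
    """

    seq_id: str
    window_start: int
    structure: str


@dataclass
class G4Mask:
    """Per-nucleotide quadruplex-participation mask."""

    seq_id: str
    mask: np.ndarray  # bool, len == sequence length


@dataclass(frozen=True)
class ExperimentalG4:
    """RT-stop-defined G4: the <=60 nt immediately upstream of the stop."""

    transcript_id: str
    start: int
    end: int
    stop_position: int
    ratio: float

    def __post_init__(self) -> None:
        if self.end != self.stop_position:
            raise ValueError("end must equal stop_position")
        if not 0 <= self.start <= self.end:
            raise ValueError("invalid interval")


def wgga_pattern(linker_max: int = 6) -> re.Pattern[str]:
    """Compile the four-tract WGGA lookahead pattern.

    Lazy linker quantifiers make the first match at each offset the one with
    lexicographically minimal (l1, l2, l3) linker lengths, which keeps
    reported spans deterministic.
    """
    lk = f"(.{{0,{linker_max}}}?)"
    core = f"[AU]GGA{lk}[AU]GGA{lk}[AU]GGA{lk}[AU]GGA"
    return re.compile(f"(?=({core}))")


_WGGA_DEFAULT = wgga_pattern(6)


def scan_wgga(seq: RnaSequence | str, linker_max: int = 6) -> list[G4Match]:
    """Find all WGGA quadruplex elements, one per feasible start offset.

    Overlapping matches at distinct offsets are all reported (lookahead
    semantics). Matches are sorted by start.
    """
    if isinstance(seq, str):
        seq = RnaSequence("seq", seq)
    pat = _WGGA_DEFAULT if linker_max == 6 else wgga_pattern(linker_max)
    out = []
    for m in pat.finditer(seq.residues):
        span = m.group(1)
        linkers = tuple(len(m.group(i)) for i in (2, 3, 4))
        out.append(
            G4Match(
                seq_id=seq.id,
                start=m.start(),
                end=m.start() + len(span),
                span=span,
                linkers=linkers,  # type: ignore[arg-type]
            )
        )
    return out


def wgga_density(seq: RnaSequence | str, linker_max: int = 6) -> float:
    """WGGA-element matches per nucleotide of sequence."""
    if isinstance(seq, str):
        seq = RnaSequence("seq", seq)
    return len(scan_wgga(seq, linker_max=linker_max)) / len(seq)


def make_windows(seq_len: int, width: int = 80, step: int = 20) -> list[int]:
    """Start offsets of sliding windows covering a sequence.

    Windows of ``width`` nt slide ``step`` nt at a time. If the last regular
    window does not reach the 3' end, a final window anchored at
    ``seq_len - width`` is appended so terminal nucleotides are covered.
    A sequence shorter than ``width`` gets a single whole-sequence window.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    if seq_len < width:
        return [0]
    starts = list(range(0, seq_len - width + 1, step))
    if starts[-1] + width < seq_len:
        starts.append(seq_len - width)
    return starts


def quadruplex_mask(
    seq: RnaSequence, windows: Iterable[StructureWindow]
) -> G4Mask:
    """Union the ``+`` annotations of covering windows into one mask.

    A position participates in a quadruplex if *any* window covering it is
    annotated ``+`` there (overlapping window predictions are reconciled by
    union).
    """
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    for w in windows:
        if w.seq_id != seq.id:
            raise ValueError(f"window for {w.seq_id} applied to {seq.id}")
        end = w.window_start + len(w.structure)
        if w.window_start < 0 or end > n:
            raise ValueError(
                f"{seq.id}: window [{w.window_start}, {end}) out of bounds "
                f"for length {n}"
            )
        plus = np.frombuffer(w.structure.encode(), dtype=np.uint8) == ord("+")
        mask[w.window_start:end] |= plus
    return G4Mask(seq_id=seq.id, mask=mask)


def quadruplex_g_density(seq: RnaSequence, mask: G4Mask) -> float:
    """Guanosines participating in predicted quadruplexes, per nucleotide."""
    if len(mask.mask) != len(seq):
        raise ValueError(
            f"{seq.id}: mask length {len(mask.mask)} != sequence "
            f"length {len(seq)}"
        )
    is_g = np.frombuffer(seq.residues.encode(), dtype=np.uint8) == ord("G")
    return float((is_g & mask.mask).sum()) / len(seq)


def call_rt_stop_g4(
    table: pd.DataFrame, ratio_min: float = 5.0, upstream: int = 60
) -> list[ExperimentalG4]:
    """Call experimental G4s from differential K+/Li+ RT-stop counts.

    A stop is called when ``count_K >= ratio_min * max(count_Li, 1)`` — the
    "at least `ratio_min` times more frequent in potassium" rule with the Li
    count floored at 1 to avoid infinite ratios. The G4 interval is the
    ``upstream`` nt immediately 5' of the stop: ``[max(0, pos-upstream), pos)``.

    ``table`` needs columns transcript_id, position, count_K, count_Li.
    """
    if len(table) == 0:
        return []
    if (table["count_K"] < 0).any() or (table["count_Li"] < 0).any():
        raise ValueError("negative RT-stop counts")
    li_floor = np.maximum(table["count_Li"].to_numpy(), 1)
    ratio = table["count_K"].to_numpy() / li_floor
    called = table.loc[ratio >= ratio_min]
    ratios = ratio[ratio >= ratio_min]
    out = []
    for (tid, pos), r in zip(
        called[["transcript_id", "position"]].itertuples(index=False), ratios
    ):
        pos = int(pos)
        out.append(
            ExperimentalG4(
                transcript_id=str(tid),
                start=max(0, pos - upstream),
                end=pos,
                stop_position=pos,
                ratio=float(r),
            )
        )
    out.sort(key=lambda g: (g.transcript_id, g.start))
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def experimental_overlap_density(
    region_start: int,
    region_end: int,
    g4s: Sequence[ExperimentalG4 | tuple[int, int]],
) -> float:
    """Basepairs of a region covered by the union of G4 intervals, per nt."""
    if region_end <= region_start:
        raise ValueError("empty region")
    clipped = []
    for g in g4s:
        s, e = (g.start, g.end) if isinstance(g, ExperimentalG4) else g
        s, e = max(s, region_start), min(e, region_end)
        if e > s:
            clipped.append((s, e))
    return _union_length(clipped) / (region_end - region_start)
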
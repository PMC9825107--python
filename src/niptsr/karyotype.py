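"""Foetal karyotype prediction from haplotype calls at breakpoint windows.

The foetus carries the rearrangement iff it inherited the carrier
parent's Hap0 (rearranged-linked) haplotype across the breakpoint
regions.  Each breakpoint is called from the posterior LOR of the
carrier-parent chain inside a flanking window, gated on a minimum number
of informative SNPs, a minimum absolute mean LOR, and the absence of a
crossover inside the window; the per-window calls combine into:

* ``normal`` — every window calls Hap1,
* ``balanced_carrier`` — every window calls Hap0,
* ``possible_unbalanced`` — windows disagree (e.g. adjacent segregation
  of a translocation, or a recombinant inversion product); this label is
  an extension and is not validated against clinical outcomes,
* ``no_call`` — any window fails its quality gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import Breakpoint, Rearrangement
from .hmm import PosteriorTrack

__all__ = [
    "BreakpointWindow",
    "WindowCall",
    "KaryotypePrediction",
    "breakpoint_windows",
    "call_breakpoint_window",
    "call_karyotype",
    "DEFAULT_FLANK_BP",
    "DEFAULT_MIN_SNPS",
    "DEFAULT_LOR_THRESHOLD",
]

DEFAULT_FLANK_BP = 5_000_000
#: minimum informative SNPs per window (sized from the observed density of
#: about 1.63 informative SNPs per Mb over a 10 Mb window, rounded down)
DEFAULT_MIN_SNPS = 8
DEFAULT_LOR_THRESHOLD = float(np.log(100.0))


@dataclass(frozen=True)
class BreakpointWindow:
    """The genomic window over which one breakpoint is called."""

    breakpoint_id: str
    chrom: str
    start: int
    end: int


def breakpoint_windows(
    rearrangement: Rearrangement, flank_bp: int = DEFAULT_FLANK_BP
) -> list[BreakpointWindow]:
    """Calling windows for a rearrangement's breakpoints.

    Reciprocal translocations and inversions use symmetric flanks
    (breakpoint ± ``flank_bp``).  Robertsonian breakpoints are
    pericentromeric on acrocentrics whose short arms carry no reliable
    panel SNPs, so only the q-proximal side (rightwards flank) is used.
    """
    wins = []
    for bp in rearrangement.breakpoints:
        if rearrangement.kind == "robertsonian":
            start, end = bp.start, bp.end + flank_bp
        else:
            start, end = max(0, bp.start - flank_bp), bp.end + flank_bp
        wins.append(BreakpointWindow(bp.id, bp.chrom, start, end))
    return wins


@dataclass
class WindowCall:
    """Aggregated evidence and call for one breakpoint window."""

    breakpoint_id: str
    chrom: str
    window: tuple[int, int]
    n_informative_snps: int
    mean_lor: float
    call: str  # Hap0 | Hap1 | no_call
    crossover_in_window: bool = False
    reason: str | None = None

    def flipped(self) -> "WindowCall":
        """The same call under a global Hap0/Hap1 relabelling."""
        swap = {"Hap0": "Hap1", "Hap1": "Hap0"}
        return WindowCall(
            breakpoint_id=self.breakpoint_id,
            chrom=self.chrom,
            window=self.window,
            n_informative_snps=self.n_informative_snps,
            mean_lor=-self.mean_lor,
            call=swap.get(self.call, self.call),
            crossover_in_window=self.crossover_in_window,
            reason=self.reason,
        )

    def to_dict(self) -> dict:
        return {
            "breakpoint_id": self.breakpoint_id,
            "chrom": self.chrom,
            "window_start": self.window[0],
            "window_end": self.window[1],
            "n_informative_snps": self.n_informative_snps,
            "mean_lor": self.mean_lor,
            "call": self.call,
            "crossover_in_window": self.crossover_in_window,
            "reason": self.reason,
        }


def call_breakpoint_window(
    track: PosteriorTrack,
    window: BreakpointWindow | Breakpoint,
    min_snps: int = DEFAULT_MIN_SNPS,
    lor_threshold: float = DEFAULT_LOR_THRESHOLD,
) -> WindowCall:
    """Call Hap0/Hap1 transmission inside one breakpoint window.

    Aggregates the per-SNP posterior LOR of the carrier-parent chain over
    SNPs inside the window and calls by the sign of the mean LOR, gated
    to ``no_call`` when the window holds fewer than ``min_snps`` SNPs,
    when ``|mean LOR| < lor_threshold``, or when a Viterbi crossover
    interval overlaps the window.
    """
    if isinstance(window, Breakpoint):
        window = BreakpointWindow(window.id, window.chrom, window.start, window.end)
    if track.chrom != window.chrom:
        return WindowCall(
            window.breakpoint_id, window.chrom, (window.start, window.end),
            0, float("nan"), "no_call", reason="track does not cover window chromosome",
        )
    if track.state_labels != ("Hap0", "Hap1"):
        raise ValueError("window calling requires a Hap0/Hap1-labelled track")

    inside = (track.positions >= window.start) & (track.positions < window.end)
    n = int(inside.sum())
    mean_lor = float(np.mean(track.lor[inside])) if n else float("nan")
    crossover = any(
        co.end > window.start and co.start < window.end for co in track.crossovers
    )

    if n == 0:
        return WindowCall(window.breakpoint_id, window.chrom,
                          (window.start, window.end), 0, float("nan"),
                          "no_call", crossover, "window outside panel coverage")
    if n < min_snps:
        return WindowCall(window.breakpoint_id, window.chrom,
                          (window.start, window.end), n, mean_lor,
                          "no_call", crossover, f"fewer than {min_snps} informative SNPs")
    if crossover:
        return WindowCall(window.breakpoint_id, window.chrom,
                          (window.start, window.end), n, mean_lor,
                          "no_call", True, "crossover inside window")
    if abs(mean_lor) < lor_threshold:
        return WindowCall(window.breakpoint_id, window.chrom,
                          (window.start, window.end), n, mean_lor,
                          "no_call", False, "mean LOR below confidence threshold")
    call = "Hap0" if mean_lor > 0 else "Hap1"
    return WindowCall(window.breakpoint_id, window.chrom,
                      (window.start, window.end), n, mean_lor, call)


@dataclass
class KaryotypePrediction:
    """The combined per-case prediction with its per-window evidence."""

    call: str  # normal | balanced_carrier | possible_unbalanced | no_call
    window_calls: list[WindowCall]
    carrier_parent: str
    rearrangement: Rearrangement = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "carrier_parent": self.carrier_parent,
            "rearrangement": self.rearrangement.to_dict(),
            "windows": [w.to_dict() for w in self.window_calls],
            "note": (
                "possible_unbalanced is an extension label, not validated "
                "against clinical outcomes"
                if self.call == "possible_unbalanced"
                else None
            ),
        }


def call_karyotype(
    window_calls: list[WindowCall], rearrangement: Rearrangement
) -> KaryotypePrediction:
    """Combine per-breakpoint window calls into the foetal karyotype.

    Requires exactly one window call per breakpoint of the
    rearrangement.
    """
    if len(window_calls) != len(rearrangement.breakpoints):
        raise ValueError(
            f"{rearrangement.kind} has {len(rearrangement.breakpoints)} breakpoints "
            f"but {len(window_calls)} window calls were supplied"
        )
    calls = {w.call for w in window_calls}
    if "no_call" in calls:
        overall = "no_call"
    elif calls == {"Hap1"}:
        overall = "normal"
    elif calls == {"Hap0"}:
        overall = "balanced_carrier"
    else:
        overall = "possible_unbalanced"
    return KaryotypePrediction(
        call=overall,
        window_calls=list(window_calls),
        carrier_parent=rearrangement.carrier_parent,
        rearrangement=rearrangement,
    )
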
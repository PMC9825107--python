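"""Two-state hidden Markov chain over informative SNPs.

One chain per (parent, chromosome): the hidden state at each informative
SNP is which of the parent's two phased haplotypes the foetus inherited
there; the state switches between adjacent SNPs with the Haldane
map-function probability r(d) = ½·(1 − e^(−2·c·d)) for inter-SNP distance
d (Morgans per Mb rate ``c``).  Emissions are binomial plasma-count
likelihoods under the state-specific expected alt fraction.  Forward–
backward yields per-SNP posterior log-odds; Viterbi yields the most
probable haplotype segmentation, whose state changes are the candidate
crossovers.

Sign convention for the posterior log-odds (LOR): on chromosomes where
the haplotypes carry Hap0/Hap1 labels, LOR = ln P(Hap0 | data) −
ln P(Hap1 | data), so LOR > 0 calls Hap0 (the rearranged-linked
haplotype) and LOR < 0 calls Hap1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TransitionSpec",
    "transition_prob",
    "PosteriorTrack",
    "CrossoverInterval",
    "forward_backward",
    "viterbi",
    "infer_haplotype",
    "detect_crossovers",
    "write_tracks_tsv",
    "read_tracks_tsv",
    "write_crossovers_bed",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class TransitionSpec:
    """Distance-dependent state-switch model (Haldane map function)."""

    morgans_per_mb: float = 0.01

    def __post_init__(self) -> None:
        if self.morgans_per_mb < 0:
            raise ValueError("recombination rate must be non-negative")


def transition_prob(distance_bp, spec: TransitionSpec = TransitionSpec()):
    """Haldane switch probability r(d) = 0.5·(1 − exp(−2·c·d_Mb)).

    Monotone in distance, r(0) = 0 and r(∞) = 0.5 (linkage equilibrium).
    Vectorised over ``distance_bp``.
    """
    d = np.asarray(distance_bp, dtype=float)
    if (d < 0).any():
        raise ValueError("negative inter-SNP distance")
    r = 0.5 * (1.0 - np.exp(-2.0 * spec.morgans_per_mb * d / 1e6))
    return r if r.shape else float(r)


@dataclass(frozen=True)
class CrossoverInterval:
    """A Viterbi state change localised between two informative SNPs."""

    chrom: str
    start: int  # position of the last SNP in the old state
    end: int    # position of the first SNP in the new state
    from_state: str
    to_state: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class PosteriorTrack:
    """Per-SNP posterior log-odds and Viterbi path for one parental chain."""

    parent: str
    chrom: str
    positions: np.ndarray = field(repr=False)
    lor: np.ndarray = field(repr=False)          # ln P(state0) − ln P(state1)
    log_post: np.ndarray = field(repr=False)     # (n, 2) log posterior marginals
    viterbi_path: np.ndarray = field(repr=False)  # (n,) state indices {0, 1}
    state_labels: tuple[str, str] = ("Hap0", "Hap1")
    log_likelihood: float = 0.0
    crossovers: list[CrossoverInterval] = field(default_factory=list)
    #: row indices of the chain SNPs in the case panel, when known
    panel_index: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def lor_log10(self) -> np.ndarray:
        """Base-10 log-odds, for plotting parity with clinical reports."""
        return self.lor / np.log(10.0)

    def viterbi_labels(self) -> np.ndarray:
        return np.asarray(self.state_labels, dtype=object)[self.viterbi_path]

    def map_states(self) -> np.ndarray:
        """Per-SNP marginal-MAP state indices (argmax of the posterior)."""
        return (self.lor < 0).astype(np.int64)


def _check_loglik(loglik: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    loglik = np.asarray(loglik, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if loglik.ndim != 2 or loglik.shape[1] != 2:
        raise ValueError(f"loglik must have shape (n, 2), got {loglik.shape}")
    if len(positions) != len(loglik):
        raise ValueError("positions and loglik length mismatch")
    if len(loglik) == 0:
        raise ValueError("empty chain")
    if (np.diff(positions) < 0).any():
        raise ValueError("positions must be non-decreasing")
    return loglik, positions


def _log_transition(positions: np.ndarray, spec: TransitionSpec) -> np.ndarray:
    """(n−1, 2, 2) log transition matrices between consecutive SNPs."""
    r = np.atleast_1d(transition_prob(np.diff(positions), spec))
    r = np.clip(r, 1e-300, 0.5)
    stay = np.log1p(-r)
    switch = np.log(r)
    out = np.empty((len(r), 2, 2))
    out[:, 0, 0] = out[:, 1, 1] = stay
    out[:, 0, 1] = out[:, 1, 0] = switch
    return out


def forward_backward(
    loglik: np.ndarray, positions: np.ndarray, spec: TransitionSpec = TransitionSpec()
) -> tuple[np.ndarray, float]:
    """Log-space forward–backward smoother.

    Parameters: ``loglik`` of shape (n, 2) with per-SNP emission
    log-likelihoods under the two states; ``positions`` in bp.  A uniform
    prior is placed on the first SNP.  Returns the (n, 2) log posterior
    marginals (normalised) and the total data log-likelihood.  All
    arithmetic is in log space (logaddexp), stable for chains well beyond
    10^4 SNPs.
    """
    loglik, positions = _check_loglik(loglik, positions)
    n = len(loglik)
    logT = _log_transition(positions, spec)

    alpha = np.empty((n, 2))
    alpha[0] = -LN2 + loglik[0]
    for i in range(1, n):
        trans = alpha[i - 1][:, None] + logT[i - 1]
        alpha[i] = loglik[i] + np.logaddexp(trans[0], trans[1])

    beta = np.empty((n, 2))
    beta[-1] = 0.0
    for i in range(n - 2, -1, -1):
        term = logT[i] + (loglik[i + 1] + beta[i + 1])[None, :]
        beta[i] = np.logaddexp(term[:, 0], term[:, 1])

    log_z = float(np.logaddexp(alpha[-1, 0], alpha[-1, 1]))
    log_post = alpha + beta - log_z
    # renormalise per site to kill accumulated rounding
    log_post -= np.logaddexp(log_post[:, 0], log_post[:, 1])[:, None]
    return log_post, log_z


def viterbi(
    loglik: np.ndarray, positions: np.ndarray, spec: TransitionSpec = TransitionSpec()
) -> np.ndarray:
    """Most probable state path under the same emissions and transitions."""
    loglik, positions = _check_loglik(loglik, positions)
    n = len(loglik)
    logT = _log_transition(positions, spec)

    delta = np.empty((n, 2))
    back = np.zeros((n, 2), dtype=np.int64)
    delta[0] = -LN2 + loglik[0]
    for i in range(1, n):
        scores = delta[i - 1][:, None] + logT[i - 1]  # (from, to)
        back[i] = np.argmax(scores, axis=0)
        delta[i] = loglik[i] + scores[back[i], (0, 1)]

    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta[-1]))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def infer_haplotype(
    parent: str,
    chrom: str,
    positions: np.ndarray,
    loglik: np.ndarray,
    spec: TransitionSpec = TransitionSpec(),
    state_labels: tuple[str, str] = ("Hap0", "Hap1"),
    panel_index: np.ndarray | None = None,
) -> PosteriorTrack:
    """Run smoothing + decoding for one parental chain on one chromosome.

    ``loglik[:, k]`` is the emission log-likelihood under transmission of
    haplotype ``state_labels[k]``.  The posterior LOR at each SNP is
    ``ln P(state0) − ln P(state1)``; crossover intervals are derived from
    the Viterbi path.
    """
    log_post, log_z = forward_backward(loglik, positions, spec)
    path = viterbi(loglik, positions, spec)
    track = PosteriorTrack(
        parent=parent,
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        lor=log_post[:, 0] - log_post[:, 1],
        log_post=log_post,
        viterbi_path=path,
        state_labels=state_labels,
        log_likelihood=log_z,
        panel_index=panel_index,
    )
    track.crossovers = detect_crossovers(track)
    return track


def detect_crossovers(track: PosteriorTrack) -> list[CrossoverInterval]:
    """Crossover intervals: one per Viterbi state change.

    Each interval spans from the last SNP of the old state to the first
    SNP of the new state; its midpoint is the point estimate.
    """
    path = track.viterbi_path
    change = np.flatnonzero(np.diff(path) != 0)
    return [
        CrossoverInterval(
            chrom=track.chrom,
            start=int(track.positions[i]),
            end=int(track.positions[i + 1]),
            from_state=track.state_labels[path[i]],
            to_state=track.state_labels[path[i + 1]],
        )
        for i in change
    ]


# ---------------------------------------------------------------------------
# track I/O


def write_tracks_tsv(tracks: list[PosteriorTrack], path: str | Path) -> None:
    """Write per-SNP LOR/Viterbi rows for a set of chains (1-based positions)."""
    rows = []
    for t in tracks:
        labels = t.viterbi_labels()
        for i in range(len(t)):
            rows.append(
                (t.chrom, int(t.positions[i]) + 1, t.parent,
                 t.state_labels[0], t.state_labels[1],
                 float(t.lor[i]), labels[i])
            )
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "parent", "state0", "state1", "lor", "viterbi_state"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tracks_tsv(path: str | Path) -> list[PosteriorTrack]:
    """Rebuild tracks from :func:`write_tracks_tsv` output.

    Posterior marginals are reconstituted from the stored LOR; the
    Viterbi path is read back as stored.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    tracks = []
    for (parent, chrom), sub in raw.groupby(["parent", "chrom"], sort=False):
        lor = sub["lor"].to_numpy(dtype=float)
        lp0 = -np.logaddexp(0.0, -lor)
        lp1 = -np.logaddexp(0.0, lor)
        labels = (str(sub["state0"].iloc[0]), str(sub["state1"].iloc[0]))
        vit = (sub["viterbi_state"].to_numpy() == labels[1]).astype(np.int64)
        track = PosteriorTrack(
            parent=str(parent),
            chrom=str(chrom),
            positions=sub["pos"].to_numpy(dtype=np.int64) - 1,
            lor=lor,
            log_post=np.column_stack([lp0, lp1]),
            viterbi_path=vit,
            state_labels=labels,
        )
        track.crossovers = detect_crossovers(track)
        tracks.append(track)
    return tracks


def write_crossovers_bed(tracks: list[PosteriorTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for k, co in enumerate(t.crossovers):
                fh.write(
                    f"{co.chrom}\t{co.start}\t{co.end}\t"
                    f"{t.parent}_co{k + 1}_{co.from_state}>{co.to_state}\n"
                )
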
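"""SNP capture panel: marker container, MAF/VIF filtering and spacing stats.

The assay genotypes a genome-wide capture panel of common biallelic SNPs
(minor allele frequency above 0.3) chosen so that neighbouring markers are
roughly 40 kb apart and not mutually redundant (variance inflation factor
at most 1.5 against nearby retained markers).  High-MAF, well-spaced,
low-collinearity markers maximise the number of sites that end up
informative for haplotype dosage in any given family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPMarker",
    "PanelDesign",
    "Panel",
    "EmptyPanelError",
    "filter_panel",
    "spacing_stats",
    "SpacingStats",
]

_BASES = {"A", "C", "G", "T"}


class EmptyPanelError(ValueError):
    """Raised when filtering or construction would produce an empty panel."""


@dataclass(frozen=True)
class SNPMarker:
    """A single biallelic panel SNP.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    pos : int
        0-based position (VCF/TSV I/O converts to and from 1-based).
    ref_allele, alt_allele : str
        Single-base alleles; must differ.
    maf : float
        Population minor allele frequency, in [0, 0.5].
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"MAF {self.maf} outside [0, 0.5] at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _BASES
            and self.alt_allele in _BASES
        )


@dataclass(frozen=True)
class PanelDesign:
    """Panel design constraints: MAF floor, VIF ceiling, target spacing."""

    maf_min: float = 0.3
    vif_max: float = 1.5
    target_median_spacing_bp: int = 40_000
    #: number of previously retained neighbours used in the VIF regression
    vif_window: int = 20


class Panel:
    """An ordered, deduplicated set of panel SNPs.

    Wraps a :class:`pandas.DataFrame` with columns ``chrom, pos, ref, alt,
    maf`` (``pos`` 0-based), sorted by (chrom, pos) with unique positions.
    """

    COLUMNS = ("chrom", "pos", "ref", "alt", "maf")

    def __init__(self, df: pd.DataFrame, design: PanelDesign | None = None,
                 meta: dict | None = None):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"panel frame missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise EmptyPanelError("panel has no markers")
        df = (
            df.loc[:, list(self.COLUMNS)]
            .drop_duplicates(subset=["chrom", "pos"], keep="first")
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df
        self.design = design or PanelDesign()
        self.meta = meta or {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_markers(cls, markers: Iterable[SNPMarker],
                     design: PanelDesign | None = None) -> "Panel":
        rows = [(m.chrom, m.pos, m.ref_allele, m.alt_allele, m.maf) for m in markers]
        if not rows:
            raise EmptyPanelError("no markers supplied")
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)), design)

    def markers(self) -> list[SNPMarker]:
        return [
            SNPMarker(r.chrom, int(r.pos), r.ref, r.alt, float(r.maf))
            for r in self.df.itertuples(index=False)
        ]

    # -- basics --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Integer row indices of markers on ``chrom``."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with 1-based positions (chrom, pos, ref, alt, maf)."""
        out = self.df.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, design: PanelDesign | None = None) -> "Panel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["pos"] = df["pos"].astype(np.int64) - 1
        return cls(df, design)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.ref}/{r.alt}\t{r.maf:.4f}\n")

    def design_to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "maf_min": self.design.maf_min,
                    "vif_max": self.design.vif_max,
                    "target_median_spacing_bp": self.design.target_median_spacing_bp,
                    "vif_window": self.design.vif_window,
                },
                fh,
                indent=2,
            )


def _vif(y: np.ndarray, X: np.ndarray) -> float:
    """Variance inflation factor of genotype vector ``y`` against columns of ``X``.

    VIF = 1 / (1 - R^2) from an ordinary least-squares regression with
    intercept.  Returns ``inf`` for (numerically) perfect collinearity and
    1.0 when there are no predictors.
    """
    if X.shape[1] == 0:
        return 1.0
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0.0:  # monomorphic in the cohort: no inflation measurable
        return 1.0
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def filter_panel(
    candidates: Sequence[SNPMarker] | Panel | pd.DataFrame,
    genotypes: np.ndarray | None = None,
    maf_min: float = 0.3,
    vif_max: float = 1.5,
    vif_window: int = 20,
) -> Panel:
    """Apply the panel design filters to candidate markers.

    Parameters
    ----------
    candidates
        Sorted candidate markers (list of :class:`SNPMarker`, a
        :class:`Panel`, or an equivalent DataFrame).
    genotypes
        Optional reference-cohort genotype matrix, shape
        ``(n_samples, n_candidates)`` with dosage coding 0/1/2, column
        order matching ``candidates``.  Required for VIF pruning; when
        omitted only the MAF and biallelic filters run.
    maf_min
        Strict minor-allele-frequency floor: a marker is kept only if
        ``maf > maf_min``.
    vif_max
        Ceiling on the variance inflation factor of each marker regressed
        on the previously retained markers within a sliding window on the
        same chromosome (greedy left-to-right retention).
    vif_window
        Number of retained upstream neighbours entering the regression.

    Returns
    -------
    Panel
        Filtered panel; ``panel.meta`` records counts of markers removed
        by each rule.
    """
    if isinstance(candidates, Panel):
        markers = candidates.markers()
    elif isinstance(candidates, pd.DataFrame):
        markers = Panel(candidates).markers()
    else:
        markers = list(candidates)
    if not markers:
        raise EmptyPanelError("no candidate markers to filter")
    if genotypes is not None:
        genotypes = np.asarray(genotypes, dtype=float)
        if genotypes.ndim != 2 or genotypes.shape[1] != len(markers):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(markers)} candidates"
            )
        if genotypes.shape[0] < 2:
            raise ValueError("VIF pruning needs a cohort of at least 2 samples")

    order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos))
    n_nonbiallelic = 0
    n_low_maf = 0
    n_vif = 0
    seen: set[tuple[str, int]] = set()
    kept_idx: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}

    for i in order:
        m = markers[i]
        key = (m.chrom, m.pos)
        if key in seen:
            continue
        seen.add(key)
        if not m.is_biallelic_snv:
            n_nonbiallelic += 1
            continue
        if not (m.maf > maf_min):
            n_low_maf += 1
            continue
        if genotypes is not None:
            prev = kept_by_chrom.get(m.chrom, [])[-vif_window:]
            vif = _vif(genotypes[:, i], genotypes[:, prev])
            if vif > vif_max:
                n_vif += 1
                continue
        kept_idx.append(i)
        kept_by_chrom.setdefault(m.chrom, []).append(i)

    if not kept_idx:
        raise EmptyPanelError("all candidate markers removed by filtering")

    design = PanelDesign(maf_min=maf_min, vif_max=vif_max, vif_window=vif_window)
    panel = Panel.from_markers([markers[i] for i in kept_idx], design)
    panel.meta = {
        "n_candidates": len(markers),
        "n_removed_nonbiallelic": n_nonbiallelic,
        "n_removed_maf": n_low_maf,
        "n_removed_vif": n_vif,
        "n_retained": len(kept_idx),
        "retained_indices": kept_idx,
    }
    return panel


@dataclass
class SpacingStats:
    """Neighbour-distance summary for a panel."""

    median_bp: float
    mean_bp: float
    max_bp: float
    n_distances: int
    per_chromosome: pd.DataFrame = field(repr=False)
    singleton_chromosomes: list[str] = field(default_factory=list)


def spacing_stats(panel: Panel) -> SpacingStats:
    """Distances between consecutive same-chromosome markers.

    Cross-chromosome pairs contribute nothing; chromosomes with a single
    marker are excluded and listed in ``singleton_chromosomes``.
    """
    rows = []
    all_gaps: list[np.ndarray] = []
    singletons: list[str] = []
    for chrom in panel.chromosomes:
        pos = panel.positions(chrom)
        if len(pos) < 2:
            singletons.append(chrom)
            continue
        gaps = np.diff(pos)
        all_gaps.append(gaps)
        rows.append(
            {
                "chrom": chrom,
                "n_markers": len(pos),
                "median_bp": float(np.median(gaps)),
                "mean_bp": float(np.mean(gaps)),
                "max_bp": float(np.max(gaps)),
            }
        )
    if not all_gaps:
        raise EmptyPanelError("no chromosome has two or more markers")
    gaps = np.concatenate(all_gaps)
    return SpacingStats(
        median_bp=float(np.median(gaps)),
        mean_bp=float(np.mean(gaps)),
        max_bp=float(np.max(gaps)),
        n_distances=int(len(gaps)),
        per_chromosome=pd.DataFrame(rows),
        singleton_chromosomes=singletons,
    )
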
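"""Maternal plasma counts, foetal-fraction estimation and the emission model.

Maternal plasma cfDNA is a mixture: a fraction ``1 − ff`` of fragments is
maternal and a fraction ``ff`` foetal (placental).  At a SNP where the
mother carries ``m`` alt alleles and the foetus ``f`` (each in {0,1,2}),
the expected alt-read fraction is

    theta_raw = (1 − ff) · m/2 + ff · f/2

and with a symmetric per-base error rate ``eps`` the observed expectation
becomes ``theta = theta_raw·(1 − eps) + (1 − theta_raw)·eps``.  Read
counts at a site are modelled as Binomial(depth, theta); overdispersion
is not modelled (extension point).

The foetal fraction is estimated from sites where the parents are
homozygous for opposite alleles, making the foetus an obligate
heterozygote: the plasma alt fraction there is ``ff/2`` away from the
maternal homozygous expectation, so twice the deviation estimates ``ff``
per site, and the median across sites is robust to outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .families import GenotypeSet

__all__ = [
    "PlasmaCounts",
    "FoetalFraction",
    "FoetalFractionError",
    "estimate_ff",
    "emission_theta",
    "theta_for_state",
    "emission_loglik",
    "DEFAULT_EPSILON",
    "CLINICAL_FF_RANGE",
]

#: default sequencing error rate (fraction); targeted capture libraries
#: show roughly 0.11% per-base error
DEFAULT_EPSILON = 0.0011

#: foetal-fraction range observed clinically in this assay's cohort class;
#: estimates outside it raise a warning flag (not an error)
CLINICAL_FF_RANGE = (0.046, 0.367)


class FoetalFractionError(RuntimeError):
    """Too few usable sites to estimate ff; supply an external value."""


@dataclass
class PlasmaCounts:
    """Per-SNP read counts from maternal plasma sequencing.

    ``df`` columns: ``chrom, pos, depth, alt_count`` aligned with the
    case panel; ``epsilon`` is the per-base sequencing error rate.
    """

    df: pd.DataFrame = field(repr=False)
    epsilon: float = DEFAULT_EPSILON
    gestational_age_weeks: float | None = None

    def __post_init__(self) -> None:
        missing = {"chrom", "pos", "depth", "alt_count"} - set(self.df.columns)
        if missing:
            raise ValueError(f"plasma frame missing columns: {sorted(missing)}")
        d = self.df["depth"].to_numpy()
        a = self.df["alt_count"].to_numpy()
        if (d < 0).any() or (a < 0).any() or (a > d).any():
            raise ValueError("require 0 <= alt_count <= depth at every site")
        if not (0.0 <= self.epsilon <= 0.01):
            raise ValueError(f"epsilon {self.epsilon} outside [0, 0.01]")

    def __len__(self) -> int:
        return len(self.df)

    def depths(self) -> np.ndarray:
        return self.df["depth"].to_numpy()

    def alt_counts(self) -> np.ndarray:
        return self.df["alt_count"].to_numpy()

    def to_tsv(self, path: str | Path, panel_df: pd.DataFrame | None = None) -> None:
        """Write counts as TSV (chrom, pos 1-based, ref, alt, ref_count, alt_count)."""
        out = self.df.copy()
        if panel_df is not None:
            out["ref"] = panel_df["ref"].to_numpy()
            out["alt"] = panel_df["alt"].to_numpy()
        else:
            out["ref"] = "N"
            out["alt"] = "N"
        out["pos"] = out["pos"] + 1
        out["ref_count"] = out["depth"] - out["alt_count"]
        out[["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]].to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, epsilon: float = DEFAULT_EPSILON) -> "PlasmaCounts":
        raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["pos"].astype(np.int64) - 1,
                "depth": (raw["ref_count"] + raw["alt_count"]).astype(np.int64),
                "alt_count": raw["alt_count"].astype(np.int64),
            }
        )
        return cls(df=df, epsilon=epsilon)


@dataclass
class FoetalFraction:
    """Foetal-fraction estimate with per-site dispersion diagnostics."""

    ff: float
    n_sites_used: int
    per_site: np.ndarray = field(repr=False)
    out_of_clinical_range: bool = False

    @property
    def iqr(self) -> float:
        lo, hi = np.percentile(self.per_site, [25, 75])
        return float(hi - lo)


def estimate_ff(
    plasma: PlasmaCounts,
    genotypes: GenotypeSet,
    min_sites: int = 10,
) -> FoetalFraction:
    """Estimate the foetal fraction from opposite-homozygote parental sites.

    At mother ref/ref + father alt/alt sites the per-site estimate is
    ``2 · alt_count/depth``; at mother alt/alt + father ref/ref sites it
    is ``2 · (1 − alt_count/depth)``; the estimate is the median across
    sites with nonzero depth.  Fewer than ``min_sites`` usable sites
    raises :class:`FoetalFractionError` (fall back to a user-supplied
    value).  The estimate is symmetric under a joint ref/alt relabelling.
    """
    m = genotypes.dosages("mother")
    f = genotypes.dosages("father")
    depth = plasma.depths().astype(float)
    alt = plasma.alt_counts().astype(float)

    usable = depth > 0
    m0f2 = (m == 0) & (f == 2) & usable
    m2f0 = (m == 2) & (f == 0) & usable

    est = np.concatenate(
        [
            2.0 * alt[m0f2] / depth[m0f2],
            2.0 * (1.0 - alt[m2f0] / depth[m2f0]),
        ]
    )
    if len(est) < min_sites:
        raise FoetalFractionError(
            f"only {len(est)} opposite-homozygote sites with coverage "
            f"(need >= {min_sites}); supply the foetal fraction externally"
        )
    ff = float(np.median(est))
    lo, hi = CLINICAL_FF_RANGE
    return FoetalFraction(
        ff=ff,
        n_sites_used=int(len(est)),
        per_site=est,
        out_of_clinical_range=not (lo <= ff <= hi),
    )


def emission_theta(maternal_dosage, foetal_dosage, ff: float, eps: float):
    """Expected plasma alt-read fraction for given maternal/foetal dosages.

    Accepts scalars or arrays.  ``theta_raw = (1-ff)·m/2 + ff·f/2``,
    then a symmetric error flip: ``theta_raw·(1-eps) + (1-theta_raw)·eps``.
    """
    if not (0.0 <= ff < 1.0):
        raise ValueError(f"ff {ff} outside [0, 1)")
    m = np.asarray(maternal_dosage, dtype=float)
    f = np.asarray(foetal_dosage, dtype=float)
    theta_raw = (1.0 - ff) * m / 2.0 + ff * f / 2.0
    theta = theta_raw * (1.0 - eps) + (1.0 - theta_raw) * eps
    return theta if theta.shape else float(theta)


def theta_for_state(
    chain_parent: str,
    mother_gt: int,
    father_gt: int,
    transmitted_allele: int,
    ff: float,
    eps: float,
) -> float:
    """theta under a hidden transmission state at one informative SNP.

    ``chain_parent`` is the heterozygous parent whose transmission the
    state describes; the other parent must be homozygous there (that is
    what makes the SNP informative), so the foetal genotype is fully
    determined by ``transmitted_allele`` (0 = ref, 1 = alt).
    """
    if transmitted_allele not in (0, 1):
        raise ValueError(f"transmitted_allele must be 0|1, got {transmitted_allele}")
    if chain_parent == "mother":
        if mother_gt != 1 or father_gt not in (0, 2):
            raise ValueError(
                "maternal chain requires mother heterozygous and father homozygous"
            )
        foetal = transmitted_allele + father_gt // 2
    elif chain_parent == "father":
        if father_gt != 1 or mother_gt not in (0, 2):
            raise ValueError(
                "paternal chain requires father heterozygous and mother homozygous"
            )
        foetal = transmitted_allele + mother_gt // 2
    else:
        raise ValueError(f"chain_parent must be mother|father, got {chain_parent!r}")
    return emission_theta(mother_gt, foetal, ff, eps)


def emission_loglik(alt_count, depth, theta):
    """Binomial log-likelihood of the observed alt count.

    Vectorised; zero-depth sites contribute log-likelihood 0 (no
    information).
    """
    alt = np.asarray(alt_count)
    d = np.asarray(depth)
    th = np.asarray(theta, dtype=float)
    ll = np.where(d > 0, stats.binom.logpmf(alt, np.maximum(d, 1), th), 0.0)
    return ll if ll.shape else float(ll)
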
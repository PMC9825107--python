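"""Informative-SNP classification and family-based parental phasing.

Haplotype dosage in maternal plasma can only be read at *informative*
SNPs: sites where exactly one parent is heterozygous and the other is
homozygous, so that any shift of the plasma allele balance away from the
homozygous-parent expectation is attributable to the heterozygous
parent's transmitted allele.  To chain those per-SNP signals into a
haplotype, the heterozygous parent must additionally be *phased* at the
site, which is what the typed relative provides:

* grandparent route — at sites where the carrier parent is heterozygous
  and the grandparent homozygous, the grandparent's allele necessarily
  sits on the grandparent-derived haplotype (this holds even if the
  grandparent's own meiosis recombined, because a homozygote transmits
  the same allele either way);
* child/sibling route — at sites where a parent is heterozygous and the
  allele that parent transmitted to the existing child is unambiguous
  (other parent homozygous, or the child homozygous), that allele sits on
  the child-transmitted haplotype.  The child-transmitted "haplotype" is
  a true haplotype only up to crossovers in the child's own meiosis; the
  downstream HMM absorbs such phase switches as extra state changes.

After phasing, the carrier parent's haplotypes on the breakpoint
chromosomes are labelled Hap0 (linked to the rearranged chromosome) and
Hap1 (linked to the structurally normal one) using the reference's
karyotype: a carrier reference shares Hap0 with the carrier parent, a
non-carrier reference shares Hap1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .families import MISSING, GenotypeSet, Pedigree, Rearrangement

__all__ = [
    "InformativeClass",
    "PhasedParent",
    "PhasingError",
    "LabelingError",
    "classify_informative",
    "phase_parent",
    "label_hap0",
    "DEFAULT_FLANK_BP",
]

#: default breakpoint flank used for the minimum-coverage sanity check
DEFAULT_FLANK_BP = 5_000_000

MATERNAL = "maternal_informative"
PATERNAL = "paternal_informative"
PHASE_ONLY = "phase_informative"
UNINFORMATIVE = "uninformative"


class PhasingError(RuntimeError):
    """Fatal phasing failure (e.g. no phased SNPs in a breakpoint flank)."""


class LabelingError(RuntimeError):
    """Hap0/Hap1 labelling impossible (missing reference karyotype)."""


@dataclass
class InformativeClass:
    """Per-SNP informativeness classes and their counts.

    ``df`` has columns ``chrom, pos, klass`` aligned with the panel;
    classes are ``maternal_informative`` (mother het, father hom),
    ``paternal_informative`` (father het, mother hom),
    ``phase_informative`` (both parents het but the reference homozygous,
    usable for phase but not for dosage) and ``uninformative``.
    """

    df: pd.DataFrame = field(repr=False)
    counts: dict[str, int] = field(default_factory=dict)

    def mask(self, klass: str) -> np.ndarray:
        return (self.df["klass"] == klass).to_numpy()


def classify_informative(genotypes: GenotypeSet, pedigree: Pedigree) -> InformativeClass:
    """Assign every panel SNP exactly one informativeness class.

    Missing genotypes in mother or father make a site uninformative.
    Class counts are independent of SNP input order (the classification
    is per-site).
    """
    m = genotypes.dosages("mother")
    f = genotypes.dosages("father")
    r = genotypes.dosages("reference")

    m_het = m == 1
    f_het = f == 1
    m_hom = (m == 0) | (m == 2)
    f_hom = (f == 0) | (f == 2)
    r_hom = (r == 0) | (r == 2)

    klass = np.full(len(genotypes), UNINFORMATIVE, dtype=object)
    klass[m_het & f_hom] = MATERNAL
    klass[f_het & m_hom] = PATERNAL
    klass[m_het & f_het & r_hom] = PHASE_ONLY

    df = genotypes.df[["chrom", "pos"]].copy()
    df["klass"] = klass
    counts = {k: int((klass == k).sum()) for k in (MATERNAL, PATERNAL, PHASE_ONLY, UNINFORMATIVE)}
    return InformativeClass(df=df, counts=counts)


@dataclass
class PhasedParent:
    """Two phased haplotype allele vectors for one parent.

    ``df`` columns: ``chrom, pos, a1, a2`` where ``a1`` is the
    reference-concordant allele (grandparent-derived, or transmitted to
    the reference child) and ``a2`` its complement; −1 marks unphased
    sites.  At every phased site {a1, a2} is a permutation of the
    parent's two genotype alleles.

    ``hap0_side`` maps each breakpoint chromosome to ``"a1"`` or ``"a2"``
    once :func:`label_hap0` has run; chromosomes without a breakpoint
    carry no Hap0/Hap1 labels.
    """

    parent: str
    df: pd.DataFrame = field(repr=False)
    hap0_side: dict[str, str] = field(default_factory=dict)
    n_candidates: int = 0
    n_phased: int = 0
    n_conflicts: int = 0

    @property
    def conflict_rate(self) -> float:
        denom = self.n_candidates + self.n_conflicts
        return self.n_conflicts / denom if denom else 0.0

    def phased_mask(self) -> np.ndarray:
        return (self.df["a1"].to_numpy() >= 0)

    def is_labelled(self, chrom: str) -> bool:
        return chrom in self.hap0_side

    def hap_alleles(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(first-state, second-state) allele vectors over rows of ``chrom``.

        For labelled chromosomes the first state is Hap0 and the second
        Hap1; otherwise the arbitrary-but-fixed (a1, a2) orientation is
        returned.
        """
        sub = self.df[self.df["chrom"] == chrom]
        a1 = sub["a1"].to_numpy()
        a2 = sub["a2"].to_numpy()
        if self.hap0_side.get(chrom, "a1") == "a2":
            return a2, a1
        return a1, a2

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write phased haplotypes as TSV (1-based positions).

        Columns ``hap0_allele``/``hap1_allele`` follow the Hap0/Hap1
        labels on labelled chromosomes; on unlabelled chromosomes the
        orientation is arbitrary and ``labelled`` is 0.
        """
        rows = []
        for chrom in dict.fromkeys(self.df["chrom"]):
            h_first, h_second = self.hap_alleles(chrom)
            sub = self.df[self.df["chrom"] == chrom]
            lab = int(self.is_labelled(chrom))
            for pos, x, y in zip(sub["pos"], h_first, h_second):
                rows.append((chrom, pos + 1, x, y, lab))
        pd.DataFrame(
            rows, columns=["chrom", "pos", "hap0_allele", "hap1_allele", "labelled"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, parent: str) -> "PhasedParent":
        raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["pos"].astype(np.int64) - 1,
                "a1": raw["hap0_allele"].astype(int),
                "a2": raw["hap1_allele"].astype(int),
            }
        )
        hap0_side = {
            c: "a1"
            for c, lab in raw.groupby("chrom", sort=False)["labelled"].first().items()
            if lab
        }
        phased = (df["a1"].to_numpy() >= 0).sum()
        return cls(parent=parent, df=df, hap0_side=hap0_side,
                   n_candidates=int(phased), n_phased=int(phased))


def _phase_via_grandparent(p: np.ndarray, r: np.ndarray):
    """Phase carrier-parent alleles against a grandparent's genotypes."""
    n = len(p)
    a1 = np.full(n, MISSING, dtype=np.int64)
    a2 = np.full(n, MISSING, dtype=np.int64)
    p_het = p == 1
    r_hom = (r == 0) | (r == 2)
    ok = p_het & r_hom
    a1[ok] = (r[ok] // 2)
    a2[ok] = 1 - a1[ok]
    # Mendelian impossibility: opposite homozygotes parent vs grandparent
    conflicts = int((((p == 0) & (r == 2)) | ((p == 2) & (r == 0))).sum())
    n_candidates = int(p_het.sum())
    return a1, a2, n_candidates, conflicts


def _phase_via_offspring(p: np.ndarray, o: np.ndarray, c: np.ndarray):
    """Phase parent ``p`` by the allele it transmitted to child ``c``.

    ``o`` is the other parent.  The transmitted allele is unambiguous
    when the other parent is homozygous (subtract its obligate
    contribution) or when the child is homozygous.
    """
    n = len(p)
    a1 = np.full(n, MISSING, dtype=np.int64)
    a2 = np.full(n, MISSING, dtype=np.int64)
    conflicts = 0

    p_het = p == 1
    o_hom = (o == 0) | (o == 2)
    c_ok = (c == 0) | (c == 1) | (c == 2)

    # other parent homozygous: transmitted = child dosage - other's allele
    m1 = p_het & o_hom & c_ok
    t1 = c[m1] - o[m1] // 2
    bad1 = (t1 < 0) | (t1 > 1)
    conflicts += int(bad1.sum())
    idx1 = np.flatnonzero(m1)[~bad1]
    a1[idx1] = t1[~bad1]

    # other parent heterozygous but child homozygous: transmitted = child/2
    m2 = p_het & (o == 1) & ((c == 0) | (c == 2))
    a1[m2] = c[m2] // 2

    phased = a1 >= 0
    a2[phased] = 1 - a1[phased]
    n_candidates = int(p_het.sum())
    return a1, a2, n_candidates, conflicts


def phase_parent(
    genotypes: GenotypeSet,
    pedigree: Pedigree,
    rearrangement: Rearrangement,
    parent: str | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> PhasedParent:
    """Construct one parent's phased haplotypes from the typed reference.

    Defaults to the carrier parent.  A grandparent reference (a parent of
    the carrier) can phase only the carrier; a child/sibling reference
    phases either parent.  SNPs with a Mendelian inconsistency between
    reference and parents are dropped and counted; for the carrier
    parent, a breakpoint flank (± ``flank_bp``) containing zero phased
    SNPs is a fatal :class:`PhasingError`.
    """
    parent = parent or rearrangement.carrier_parent
    if parent not in ("mother", "father"):
        raise ValueError(f"parent must be mother|father, got {parent!r}")
    p = genotypes.dosages(parent)
    r = genotypes.dosages("reference")

    if pedigree.reference_role == "grandparent":
        if parent != rearrangement.carrier_parent:
            raise PhasingError(
                "a grandparent reference is related only to the carrier parent "
                f"and cannot phase the {parent}"
            )
        a1, a2, n_cand, n_conf = _phase_via_grandparent(p, r)
    else:
        other = "father" if parent == "mother" else "mother"
        o = genotypes.dosages(other)
        a1, a2, n_cand, n_conf = _phase_via_offspring(p, o, r)

    df = genotypes.df[["chrom", "pos"]].copy()
    df["a1"] = a1
    df["a2"] = a2
    phased = PhasedParent(
        parent=parent,
        df=df,
        n_candidates=n_cand,
        n_phased=int((a1 >= 0).sum()),
        n_conflicts=n_conf,
    )

    if parent == rearrangement.carrier_parent:
        pos = df["pos"].to_numpy()
        chroms = df["chrom"].to_numpy()
        ok = a1 >= 0
        for bp in rearrangement.breakpoints:
            in_flank = (
                (chroms == bp.chrom)
                & (pos >= bp.start - flank_bp)
                & (pos < bp.end + flank_bp)
            )
            if not (in_flank & ok).any():
                raise PhasingError(
                    f"no phased SNP within ±{flank_bp} bp of breakpoint {bp.id} "
                    f"({bp.chrom}:{bp.start}-{bp.end})"
                )
    return phased


def label_hap0(
    phased: PhasedParent,
    pedigree: Pedigree,
    rearrangement: Rearrangement,
) -> PhasedParent:
    """Attach Hap0/Hap1 labels to the carrier parent's breakpoint chromosomes.

    The reference-concordant haplotype (``a1``) is Hap0 when the
    reference is itself a carrier of the rearrangement (transmitting
    grandparent, or a child karyotyped as a balanced carrier), and Hap1
    when the reference is a non-carrier.  Requires
    ``pedigree.reference_carrier_status``; no guess is made.
    """
    if phased.parent != rearrangement.carrier_parent:
        raise LabelingError(
            f"Hap0/Hap1 labels apply to the carrier parent "
            f"({rearrangement.carrier_parent}), not the {phased.parent}"
        )
    status = pedigree.reference_carrier_status
    if status is None:
        raise LabelingError(
            "reference_carrier_status is unknown: cannot orient Hap0/Hap1"
        )
    side = "a1" if status == "carrier" else "a2"
    hap0_side = dict(phased.hap0_side)
    for chrom in rearrangement.chromosomes:
        hap0_side[chrom] = side
    return replace(phased, df=phased.df, hap0_side=hap0_side)
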
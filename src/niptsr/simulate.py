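"""Synthetic-data generator: panel, family, meiosis, and plasma counts.

Emulates the study design end to end so that every pipeline stage can be
validated against known truth:

* a capture panel of common SNPs (MAF ~ Uniform(0.3, 0.5), neighbour
  gaps drawn lognormal with median 40 kb);
* a couple in which one partner carries a balanced rearrangement
  inherited from a typed relative (grandparent) or shared with a typed
  existing child (sibling/child reference);
* meioses with Poisson crossovers at a uniform rate (Haldane-consistent,
  default 0.01 Morgans/Mb), optionally with forced crossover positions
  in the foetal meiosis;
* maternal plasma counts: per-SNP depth ~ Poisson(mean depth) and alt
  reads ~ Binomial(depth, theta) with theta from the emission model at
  the true foetal genotype, foetal fraction and error rate.

The rearrangement is represented purely as breakpoint-linked haplotype
labels — no sequence-level derivative chromosomes are built, since the
assay only ever observes SNP haplotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .families import Breakpoint, GenotypeSet, Pedigree, Rearrangement
from .genome import GRCH38_AUTOSOMES
from .panel import Panel, PanelDesign
from .plasma import PlasmaCounts, emission_theta

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_family",
    "simulate_plasma",
    "genome_panel",
    "write_case",
    "GENOME_PANEL_SIZE",
]

#: size of the genome-wide capture panel emulated by :func:`genome_panel`
GENOME_PANEL_SIZE = 65_172

_BASES = np.array(list("ACGT"))

_DEFAULT_LAYOUT = {
    # kind -> (chromosome lengths, breakpoints)
    "reciprocal_translocation": (
        {"chr1": 100_000_000, "chr2": 100_000_000},
        [("bp1", "chr1", 60_000_000, 60_010_000), ("bp2", "chr2", 30_000_000, 30_010_000)],
    ),
    "robertsonian": (
        {"chr13": 100_000_000, "chr14": 100_000_000},
        [("bp1", "chr13", 1_500_000, 1_600_000), ("bp2", "chr14", 1_500_000, 1_600_000)],
    ),
    "inversion": (
        {"chr18": 100_000_000, "chr2": 100_000_000},
        [("bp1", "chr18", 30_000_000, 30_010_000), ("bp2", "chr18", 60_000_000, 60_010_000)],
    ),
}


@dataclass
class SimConfig:
    """Scenario parameters for one simulated case.

    Defaults are the desk-scale scenario: two 100-Mb chromosomes at the
    genome-wide panel density (21.7 SNPs/Mb), plasma depth 100x, foetal
    fraction 0.2, sequencing error 0.11%.  ``seed`` fully determines the
    output.
    """

    kind: str = "reciprocal_translocation"
    carrier_parent: str = "mother"
    reference_role: str = "grandparent"
    #: grandparent route: whether the typed grandparent is the transmitting
    #: carrier.  Offspring route: "auto" derives the status from the
    #: simulated child; "carrier"/"non_carrier" conditions the child on it.
    reference_carrier_status: str = "carrier"
    chromosomes: dict[str, int] | None = None
    breakpoints: list[tuple[str, str, int, int]] | None = None
    snps_per_mb: float = 21.7
    maf_range: tuple[float, float] = (0.3, 0.5)
    gap_sigma: float = 0.4  # lognormal sigma of inter-SNP gaps (median 40 kb)
    mean_depth: float = 100.0
    ff: float = 0.2
    epsilon: float = 0.0011
    morgans_per_mb: float = 0.01
    #: {(parent, chrom): [positions]} overriding the foetal meiosis crossovers
    forced_crossovers: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_LAYOUT:
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if not (0.0 < self.ff < 1.0):
            raise ValueError(f"ff {self.ff} outside (0, 1)")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError(f"epsilon {self.epsilon} outside [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if self.chromosomes is None:
            self.chromosomes = dict(_DEFAULT_LAYOUT[self.kind][0])
        if self.breakpoints is None:
            self.breakpoints = [tuple(b) for b in _DEFAULT_LAYOUT[self.kind][1]]
        for _, chrom, start, end in self.breakpoints:
            if chrom not in self.chromosomes:
                raise ValueError(f"breakpoint chromosome {chrom} not in simulated genome")
            if end > self.chromosomes[chrom]:
                raise ValueError(f"breakpoint {chrom}:{start}-{end} off the chromosome end")

    def rearrangement(self) -> Rearrangement:
        return Rearrangement(
            kind=self.kind,
            breakpoints=tuple(
                Breakpoint(str(b[0]), str(b[1]), int(b[2]), int(b[3]))
                for b in self.breakpoints
            ),
            carrier_parent=self.carrier_parent,
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        if d["forced_crossovers"]:
            d["forced_crossovers"] = [
                {"parent": p, "chrom": c, "positions": list(v)}
                for (p, c), v in self.forced_crossovers.items()
            ]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("forced_crossovers"):
            d["forced_crossovers"] = {
                (e["parent"], e["chrom"]): list(e["positions"])
                for e in d["forced_crossovers"]
            }
        if d.get("breakpoints"):
            d["breakpoints"] = [tuple(b) for b in d["breakpoints"]]
        if d.get("maf_range"):
            d["maf_range"] = tuple(d["maf_range"])
        d.update(overrides)
        return cls(**d)


# ---------------------------------------------------------------------------
# panel generation


def _chrom_positions(rng: np.random.Generator, length: int, n: int,
                     sigma: float, offset: int = 200_000) -> np.ndarray:
    """Marker positions with lognormal neighbour gaps (median 40 kb).

    Gaps are scaled so the markers span the chromosome between telomeric
    offsets; for genome-density chromosomes the scale factor is close to
    1 and the realised median gap stays near 40 kb.
    """
    if n < 2:
        raise ValueError("need at least 2 markers per chromosome")
    gaps = rng.lognormal(mean=np.log(40_000.0), sigma=sigma, size=n)
    cum = np.cumsum(gaps)
    span = length - 2 * offset
    if span <= 0:
        raise ValueError(f"chromosome length {length} too short for offsets")
    pos = offset + cum * (span / cum[-1])
    return np.unique(pos.astype(np.int64))


def _panel_frame(rng: np.random.Generator, chromosomes: dict[str, int],
                 counts: dict[str, int], maf_range: tuple[float, float],
                 sigma: float) -> Panel:
    rows = []
    for chrom, length in chromosomes.items():
        pos = _chrom_positions(rng, length, counts[chrom], sigma)
        n = len(pos)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        maf = rng.uniform(*maf_range, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "maf": maf,
                }
            )
        )
    design = PanelDesign()
    return Panel(pd.concat(rows, ignore_index=True), design)


def desk_panel(config: SimConfig, rng: np.random.Generator) -> Panel:
    """The per-case panel at the configured density."""
    counts = {
        chrom: max(2, round(config.snps_per_mb * length / 1e6))
        for chrom, length in config.chromosomes.items()
    }
    return _panel_frame(rng, config.chromosomes, counts, config.maf_range, config.gap_sigma)


def genome_panel(n_snps: int = GENOME_PANEL_SIZE, seed: int = 0,
                 maf_range: tuple[float, float] = (0.3, 0.5),
                 gap_sigma: float = 0.4) -> Panel:
    """The default genome-wide synthetic panel fixture.

    ``n_snps`` markers are allocated to the 22 autosomes proportionally
    to GRCh38 length (largest-remainder rounding) and placed with
    lognormal gaps of median 40 kb.
    """
    rng = np.random.default_rng(seed)
    lengths = GRCH38_AUTOSOMES
    total = sum(lengths.values())
    quota = {c: n_snps * l / total for c, l in lengths.items()}
    counts = {c: int(q) for c, q in quota.items()}
    remainder = n_snps - sum(counts.values())
    for c in sorted(quota, key=lambda c: quota[c] - counts[c], reverse=True)[:remainder]:
        counts[c] += 1
    return _panel_frame(rng, lengths, counts, maf_range, gap_sigma)


# ---------------------------------------------------------------------------
# meiosis


def _side_at(start: int, xs: list[float], position: float) -> int:
    """Transmitted haplotype index at ``position`` given crossovers ``xs``."""
    return (start + sum(1 for x in xs if x < position)) % 2


def _meiosis(
    rng: np.random.Generator,
    panel: Panel,
    rate: float,
    forced: dict[str, list[float]] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[np.ndarray, dict[str, list[float]], dict[str, int]]:
    """One meiosis over the panel chromosomes.

    Returns per-SNP transmitted haplotype indices (0/1), the crossover
    positions per chromosome, and the starting haplotype per chromosome.
    Crossover counts are Poisson with mean ``rate * L_Mb`` (one Morgan =
    one expected crossover), positions uniform on the chromosome;
    ``forced`` pins the crossover positions on selected chromosomes.
    """
    indicator = np.empty(len(panel), dtype=np.int64)
    crossovers: dict[str, list[float]] = {}
    starts: dict[str, int] = {}
    for chrom in panel.chromosomes:
        idx = panel.chrom_index(chrom)
        pos = panel.df["pos"].to_numpy()[idx]
        length = (chrom_lengths or {}).get(chrom, int(pos[-1]) + 1)
        if forced is not None and chrom in forced:
            xs = sorted(float(x) for x in forced[chrom])
        else:
            k = rng.poisson(rate * length / 1e6)
            xs = sorted(rng.uniform(0, length, size=k).tolist())
        start = int(rng.integers(0, 2))
        parity = (start + np.searchsorted(np.asarray(xs), pos)) % 2
        indicator[idx] = parity
        crossovers[chrom] = xs
        starts[chrom] = start
    return indicator, crossovers, starts


# ---------------------------------------------------------------------------
# family simulation


@dataclass
class TruthSet:
    """Ground truth for one simulated case."""

    config: SimConfig
    panel: Panel = field(repr=False)
    genotypes: GenotypeSet = field(repr=False)
    pedigree: Pedigree
    rearrangement: Rearrangement
    mother_haps: np.ndarray = field(repr=False)  # (2, n)
    father_haps: np.ndarray = field(repr=False)
    #: row index (0/1) of the carrier parent's rearranged-linked haplotype
    hap0_index: int = 0
    #: foetal transmitted haplotype row per parent, (n,) each
    transmitted: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    foetal_genotype: np.ndarray = field(default=None, repr=False)
    #: foetal-meiosis crossover positions, {(parent, chrom): [pos]}
    crossovers: dict = field(default_factory=dict)
    #: reference-child meiosis crossovers (offspring route), same keying
    reference_crossovers: dict = field(default_factory=dict)
    karyotype: str = "normal"

    def parent_haps(self, parent: str) -> np.ndarray:
        return self.mother_haps if parent == "mother" else self.father_haps

    def transmitted_alleles(self, parent: str) -> np.ndarray:
        """The allele the foetus actually inherited from ``parent``, per SNP."""
        haps = self.parent_haps(parent)
        return haps[self.transmitted[parent], np.arange(haps.shape[1])]

    def expected_switch_points(self, parent: str, chrom: str) -> list[float]:
        """Positions where the inferred chain state should change.

        Foetal crossovers always switch the state.  With an offspring
        reference, the phased haplotype is the child-transmitted mosaic,
        so crossovers of the child's meiosis switch the reference frame
        as well.
        """
        pts = list(self.crossovers.get((parent, chrom), []))
        pts += list(self.reference_crossovers.get((parent, chrom), []))
        return sorted(pts)

    def to_json(self, path: str | Path) -> None:
        d = {
            "karyotype": self.karyotype,
            "hap0_index": self.hap0_index,
            "ff": self.config.ff,
            "crossovers": [
                {"parent": p, "chrom": c, "positions": v}
                for (p, c), v in self.crossovers.items()
            ],
            "reference_crossovers": [
                {"parent": p, "chrom": c, "positions": v}
                for (p, c), v in self.reference_crossovers.items()
            ],
            "transmitted": {p: v.tolist() for p, v in self.transmitted.items()},
            "mother_haps": self.mother_haps.tolist(),
            "father_haps": self.father_haps.tolist(),
            "foetal_genotype": self.foetal_genotype.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


def _draw_haps(rng: np.random.Generator, alt_freq: np.ndarray) -> np.ndarray:
    return (rng.random((2, len(alt_freq))) < alt_freq).astype(np.int64)


def simulate_family(config: SimConfig) -> TruthSet:
    """Simulate panel, founders, reference and foetal meioses for one case.

    All genotypes are Mendelian-consistent by construction and the same
    seed reproduces the output bit for bit.
    """
    rng = np.random.default_rng([config.seed, 0])
    panel = desk_panel(config, rng)
    n = len(panel)
    alt_freq = panel.df["maf"].to_numpy()  # alt allele is the minor one
    rearr = config.rearrangement()
    bp_chroms = set(rearr.chromosomes)
    bp_mid = [(b.chrom, b.midpoint) for b in rearr.breakpoints]

    mother_haps = _draw_haps(rng, alt_freq)
    father_haps = _draw_haps(rng, alt_freq)
    carrier = config.carrier_parent
    carrier_haps = mother_haps if carrier == "mother" else father_haps

    rate = config.morgans_per_mb
    lengths = config.chromosomes

    ref_crossovers: dict = {}
    if config.reference_role == "grandparent":
        status = config.reference_carrier_status
        if status not in ("carrier", "non_carrier"):
            raise ValueError(
                "grandparent reference needs reference_carrier_status carrier|non_carrier"
            )
        gp_haps = _draw_haps(rng, alt_freq)
        ind, _, _ = _meiosis(rng, panel, rate, chrom_lengths=lengths)
        gamete = gp_haps[ind, np.arange(n)]
        if status == "carrier":
            # the typed grandparent transmits the rearranged haplotype: the
            # carrier's grandparent-derived haplotype copies it wholesale on
            # the breakpoint chromosomes
            for chrom in bp_chroms:
                idx = panel.chrom_index(chrom)
                gamete[idx] = gp_haps[0, idx]
            hap0_index = 0
        else:
            hap0_index = 1
        carrier_haps[0] = gamete  # row 0 = grandparent-derived haplotype
        reference_gt = gp_haps.sum(axis=0)
        ref_status = status
    elif config.reference_role in ("sibling", "child"):
        want = config.reference_carrier_status
        if want not in ("auto", "carrier", "non_carrier"):
            raise ValueError(
                "offspring reference_carrier_status must be auto|carrier|non_carrier"
            )
        hap0_index = 0  # carrier's row 0 is the rearranged-linked haplotype
        other = "father" if carrier == "mother" else "mother"
        other_haps = mother_haps if other == "mother" else father_haps
        for _ in range(10_000):
            ind_c, xs_c, st_c = _meiosis(rng, panel, rate, chrom_lengths=lengths)
            sides = {
                _side_at(st_c[c], xs_c[c], mid) for c, mid in bp_mid
            }
            if len(sides) > 1:
                continue  # unbalanced child: not a usable (karyotyped) reference
            status = "carrier" if sides == {hap0_index} else "non_carrier"
            if want == "auto" or status == want:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a balanced reference child")
        ind_o, xs_o, _ = _meiosis(rng, panel, rate, chrom_lengths=lengths)
        reference_gt = (
            carrier_haps[ind_c, np.arange(n)] + other_haps[ind_o, np.arange(n)]
        )
        ref_crossovers = {(carrier, c): v for c, v in xs_c.items()}
        ref_crossovers.update({(other, c): v for c, v in xs_o.items()})
        ref_status = status
    else:
        raise ValueError(f"unknown reference_role {config.reference_role!r}")

    pedigree = Pedigree(
        mother="M", father="F", reference="R",
        reference_role=config.reference_role,
        reference_carrier_status=ref_status,
    )

    # foetal meioses
    forced = config.forced_crossovers or {}
    forced_by_parent = {
        p: {c: v for (pp, c), v in forced.items() if pp == p} for p in ("mother", "father")
    }
    ind_m, xs_m, st_m = _meiosis(
        rng, panel, rate, forced=forced_by_parent["mother"] or None, chrom_lengths=lengths
    )
    ind_f, xs_f, st_f = _meiosis(
        rng, panel, rate, forced=forced_by_parent["father"] or None, chrom_lengths=lengths
    )
    foetal_gt = mother_haps[ind_m, np.arange(n)] + father_haps[ind_f, np.arange(n)]

    xs_carrier = xs_m if carrier == "mother" else xs_f
    st_carrier = st_m if carrier == "mother" else st_f
    sides = [
        _side_at(st_carrier[c], xs_carrier[c], mid) for c, mid in bp_mid
    ]
    if all(s == hap0_index for s in sides):
        karyotype = "balanced_carrier"
    elif all(s != hap0_index for s in sides):
        karyotype = "normal"
    else:
        karyotype = "possible_unbalanced"

    gdf = panel.df[["chrom", "pos"]].copy()
    gdf["mother"] = mother_haps.sum(axis=0)
    gdf["father"] = father_haps.sum(axis=0)
    gdf["reference"] = reference_gt

    crossovers = {("mother", c): v for c, v in xs_m.items()}
    crossovers.update({("father", c): v for c, v in xs_f.items()})

    return TruthSet(
        config=config,
        panel=panel,
        genotypes=GenotypeSet(gdf),
        pedigree=pedigree,
        rearrangement=rearr,
        mother_haps=mother_haps,
        father_haps=father_haps,
        hap0_index=hap0_index,
        transmitted={"mother": ind_m, "father": ind_f},
        foetal_genotype=foetal_gt,
        crossovers=crossovers,
        reference_crossovers=ref_crossovers,
        karyotype=karyotype,
    )


def simulate_plasma(truth: TruthSet, config: SimConfig | None = None) -> PlasmaCounts:
    """Plasma sequencing counts for a simulated case.

    Depth is Poisson(mean depth) per SNP; alt counts are binomial with
    the emission-model expectation at the true maternal and foetal
    genotypes, foetal fraction and error rate.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    m = truth.genotypes.dosages("mother")
    theta = emission_theta(m, truth.foetal_genotype, config.ff, config.epsilon)
    depth = rng.poisson(config.mean_depth, size=len(m))
    alt = rng.binomial(depth, theta)
    df = truth.panel.df[["chrom", "pos"]].copy()
    df["depth"] = depth
    df["alt_count"] = alt
    return PlasmaCounts(df=df, epsilon=config.epsilon)


def write_case(truth: TruthSet, plasma: PlasmaCounts, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated case in the formats the pipeline reads.

    Emits panel TSV, multi-sample genotype VCF, plasma TSV, pedigree
    JSON, breakpoints BED, rearrangement JSON and a truth JSON; returns
    the path of each artefact.
    """
    from . import io as _io  # local import: io depends on cyvcf2

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": outdir / "panel.tsv",
        "genotypes": outdir / "genotypes.vcf",
        "plasma": outdir / "plasma.tsv",
        "pedigree": outdir / "pedigree.json",
        "breakpoints": outdir / "breakpoints.bed",
        "rearrangement": outdir / "rearrangement.json",
        "truth": outdir / "truth.json",
    }
    truth.panel.to_tsv(paths["panel"])
    _io.write_genotypes_vcf(paths["genotypes"], truth.panel, truth.genotypes, truth.pedigree)
    plasma.to_tsv(paths["plasma"], truth.panel.df)
    truth.pedigree.to_json(paths["pedigree"])
    from .families import write_breakpoints_bed

    write_breakpoints_bed(list(truth.rearrangement.breakpoints), paths["breakpoints"])
    with open(paths["rearrangement"], "w") as fh:
        json.dump(truth.rearrangement.to_dict(), fh, indent=2)
    truth.to_json(paths["truth"])
    return paths
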
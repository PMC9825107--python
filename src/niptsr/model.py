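"""The fitted-model interface: :class:`TransmissionModel` / results.

The model ties the pipeline together in the style of a statistical
modelling package: construct a :class:`TransmissionModel` from the case
data (panel, family genotypes, plasma counts, pedigree, rearrangement),
call :meth:`~TransmissionModel.fit`, and read estimates, diagnostics and
the karyotype prediction off the returned
:class:`TransmissionResults` (``summary()``, ``to_report()``,
``plot_lor()``).

Fitting runs, in order: informative-SNP classification; foetal-fraction
estimation (unless supplied); family-based phasing of the carrier parent
(and of the other parent when the reference is a child/sibling of the
foetus); Hap0/Hap1 labelling; one hidden Markov chain per (parent,
chromosome) over the usable SNPs; crossover detection; and breakpoint-
window karyotype calling.  Inference is deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .families import GenotypeSet, Pedigree, Rearrangement, read_breakpoints_bed
from .hmm import PosteriorTrack, TransitionSpec, infer_haplotype
from .karyotype import (
    DEFAULT_FLANK_BP,
    DEFAULT_LOR_THRESHOLD,
    DEFAULT_MIN_SNPS,
    KaryotypePrediction,
    WindowCall,
    breakpoint_windows,
    call_breakpoint_window,
    call_karyotype,
)
from .panel import Panel
from .phasing import (
    MATERNAL,
    PATERNAL,
    PhasedParent,
    classify_informative,
    label_hap0,
    phase_parent,
)
from .plasma import (
    DEFAULT_EPSILON,
    FoetalFraction,
    PlasmaCounts,
    emission_loglik,
    emission_theta,
    estimate_ff,
)

__all__ = ["TransmissionModel", "TransmissionResults"]


class TransmissionModel:
    """Foetal haplotype-transmission model for one pregnancy.

    Parameters
    ----------
    panel, genotypes, plasma
        Row-aligned case data (same SNPs in the same order).
    pedigree, rearrangement
        Family structure and the carried rearrangement.
    ff
        Foetal fraction; estimated from opposite-homozygote sites when
        ``None``.
    epsilon
        Sequencing error rate (default 0.0011).
    transition
        Recombination model for the HMM (default 0.01 Morgans/Mb,
        Haldane map).
    flank_bp, min_snps, lor_threshold
        Breakpoint-window calling parameters.
    """

    def __init__(
        self,
        panel: Panel,
        genotypes: GenotypeSet,
        plasma: PlasmaCounts,
        pedigree: Pedigree,
        rearrangement: Rearrangement,
        *,
        ff: float | None = None,
        epsilon: float | None = None,
        transition: TransitionSpec | None = None,
        flank_bp: int = DEFAULT_FLANK_BP,
        min_snps: int = DEFAULT_MIN_SNPS,
        lor_threshold: float = DEFAULT_LOR_THRESHOLD,
    ):
        for name, df in (("genotypes", genotypes.df), ("plasma", plasma.df)):
            if len(df) != len(panel):
                raise ValueError(f"{name} has {len(df)} rows, panel has {len(panel)}")
            if not (
                (df["chrom"].to_numpy() == panel.df["chrom"].to_numpy()).all()
                and (df["pos"].to_numpy() == panel.df["pos"].to_numpy()).all()
            ):
                raise ValueError(f"{name} rows are not aligned with the panel")
        for chrom in rearrangement.chromosomes:
            if chrom not in panel.chromosomes:
                raise ValueError(f"breakpoint chromosome {chrom} absent from the panel")
        if ff is not None and not (0.0 < ff < 1.0):
            raise ValueError(f"ff {ff} outside (0, 1)")
        self.panel = panel
        self.genotypes = genotypes
        self.plasma = plasma
        self.pedigree = pedigree
        self.rearrangement = rearrangement
        self.ff = ff
        self.epsilon = plasma.epsilon if epsilon is None else epsilon
        self.transition = transition or TransitionSpec()
        self.flank_bp = int(flank_bp)
        self.min_snps = int(min_snps)
        self.lor_threshold = float(lor_threshold)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_files(
        cls,
        panel: str | Path,
        genotypes_vcf: str | Path,
        plasma: str | Path,
        pedigree: str | Path,
        rearrangement: str | Path,
        breakpoints_bed: str | Path | None = None,
        *,
        epsilon: float = DEFAULT_EPSILON,
        **kwargs,
    ) -> "TransmissionModel":
        """Build a model from the on-disk case formats.

        ``rearrangement`` is the rearrangement JSON; ``breakpoints_bed``
        optionally overrides its breakpoint intervals.  All files are
        checked and parsed before any computation starts.
        """
        from . import io as _io
        import json

        for p in (panel, genotypes_vcf, plasma, pedigree, rearrangement):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        panel_obj = Panel.from_tsv(panel)
        ped = Pedigree.from_json(pedigree)
        with open(rearrangement) as fh:
            rearr = Rearrangement.from_dict(json.load(fh))
        if breakpoints_bed is not None:
            bps = read_breakpoints_bed(breakpoints_bed)
            rearr = Rearrangement(
                kind=rearr.kind,
                breakpoints=tuple(bps),
                carrier_parent=rearr.carrier_parent,
                carrier_origin=rearr.carrier_origin,
            )
        gts = _io.read_genotypes_vcf(genotypes_vcf, panel_obj, ped)
        counts = _io.read_plasma(plasma, panel_obj, epsilon)
        return cls(panel_obj, gts, counts, ped, rearr, epsilon=epsilon, **kwargs)

    # -- fitting ----------------------------------------------------------

    def _oriented_haps(self, phased: PhasedParent) -> tuple[np.ndarray, np.ndarray]:
        """Panel-aligned (state0, state1) allele vectors for one parent."""
        n = len(self.panel)
        first = np.full(n, -1, dtype=np.int64)
        second = np.full(n, -1, dtype=np.int64)
        chroms = self.panel.df["chrom"].to_numpy()
        a1 = phased.df["a1"].to_numpy()
        a2 = phased.df["a2"].to_numpy()
        for chrom in self.panel.chromosomes:
            idx = chroms == chrom
            if phased.hap0_side.get(chrom, "a1") == "a2":
                first[idx], second[idx] = a2[idx], a1[idx]
            else:
                first[idx], second[idx] = a1[idx], a2[idx]
        return first, second

    def fit(self) -> "TransmissionResults":
        """Run the full inference and return the results object."""
        informative = classify_informative(self.genotypes, self.pedigree)

        if self.ff is not None:
            ff_result = FoetalFraction(
                ff=self.ff, n_sites_used=0, per_site=np.empty(0),
                out_of_clinical_range=not (0.046 <= self.ff <= 0.367),
            )
        else:
            ff_result = estimate_ff(self.plasma, self.genotypes)
        ff = ff_result.ff
        if not (0.0 < ff < 1.0):
            raise ValueError(f"foetal fraction estimate {ff} outside (0, 1)")

        parents = [self.rearrangement.carrier_parent]
        if self.pedigree.is_offspring_reference:
            parents.append(
                "father" if parents[0] == "mother" else "mother"
            )
        phased: dict[str, PhasedParent] = {}
        for parent in parents:
            ph = phase_parent(
                self.genotypes, self.pedigree, self.rearrangement, parent,
                flank_bp=self.flank_bp,
            )
            if parent == self.rearrangement.carrier_parent:
                ph = label_hap0(ph, self.pedigree, self.rearrangement)
            phased[parent] = ph

        mother = self.genotypes.dosages("mother")
        father = self.genotypes.dosages("father")
        depth = self.plasma.depths()
        alt = self.plasma.alt_counts()
        chrom_col = self.panel.df["chrom"].to_numpy()
        pos_col = self.panel.df["pos"].to_numpy()

        tracks: list[PosteriorTrack] = []
        for parent, ph in phased.items():
            klass = MATERNAL if parent == "mother" else PATERNAL
            usable_all = informative.mask(klass) & ph.phased_mask()
            h_first, h_second = self._oriented_haps(ph)
            other_hom = (father if parent == "mother" else mother) // 2
            for chrom in self.panel.chromosomes:
                usable = usable_all & (chrom_col == chrom)
                if not usable.any():
                    continue
                idx = np.flatnonzero(usable)
                foetal0 = h_first[idx] + other_hom[idx]
                foetal1 = h_second[idx] + other_hom[idx]
                m_dos = mother[idx]
                theta = np.column_stack(
                    [
                        emission_theta(m_dos, foetal0, ff, self.epsilon),
                        emission_theta(m_dos, foetal1, ff, self.epsilon),
                    ]
                )
                loglik = np.column_stack(
                    [
                        emission_loglik(alt[idx], depth[idx], theta[:, 0]),
                        emission_loglik(alt[idx], depth[idx], theta[:, 1]),
                    ]
                )
                labelled = ph.is_labelled(chrom)
                labels = ("Hap0", "Hap1") if labelled else ("RefHap", "AltHap")
                tracks.append(
                    infer_haplotype(
                        parent, chrom, pos_col[idx], loglik,
                        spec=self.transition, state_labels=labels, panel_index=idx,
                    )
                )

        carrier = self.rearrangement.carrier_parent
        track_map = {(t.parent, t.chrom): t for t in tracks}
        window_calls: list[WindowCall] = []
        for window in breakpoint_windows(self.rearrangement, self.flank_bp):
            track = track_map.get((carrier, window.chrom))
            if track is None:
                window_calls.append(
                    WindowCall(
                        window.breakpoint_id, window.chrom,
                        (window.start, window.end), 0, float("nan"),
                        "no_call", reason="no usable SNPs on window chromosome",
                    )
                )
                continue
            window_calls.append(
                call_breakpoint_window(
                    track, window, min_snps=self.min_snps,
                    lor_threshold=self.lor_threshold,
                )
            )
        prediction = call_karyotype(window_calls, self.rearrangement)

        return TransmissionResults(
            model=self,
            ff=ff_result,
            informative=informative,
            phased=phased,
            tracks=tracks,
            window_calls=window_calls,
            prediction=prediction,
        )


@dataclass
class TransmissionResults:
    """Estimates, diagnostics and the karyotype prediction of a fit."""

    model: TransmissionModel = field(repr=False)
    ff: FoetalFraction
    informative: object = field(repr=False)
    phased: dict[str, PhasedParent] = field(repr=False)
    tracks: list[PosteriorTrack] = field(repr=False)
    window_calls: list[WindowCall] = field(default_factory=list)
    prediction: KaryotypePrediction | None = None

    @property
    def karyotype_call(self) -> str:
        return self.prediction.call

    def track(self, parent: str, chrom: str) -> PosteriorTrack | None:
        for t in self.tracks:
            if t.parent == parent and t.chrom == chrom:
                return t
        return None

    def crossovers(self) -> list:
        return [co for t in self.tracks for co in t.crossovers]

    def transmitted_alleles(self, parent: str) -> pd.DataFrame:
        """Per-SNP inferred transmitted allele for one parent's chains.

        Uses the marginal-MAP state (sign of the posterior LOR) at each
        usable SNP; columns ``chrom, pos, allele, lor``.
        """
        frames = []
        ph = self.phased[parent]
        for t in self.tracks:
            if t.parent != parent or t.panel_index is None:
                continue
            h_first, h_second = self.model._oriented_haps(ph)
            states = t.map_states()
            allele = np.where(
                states == 0, h_first[t.panel_index], h_second[t.panel_index]
            )
            frames.append(
                pd.DataFrame(
                    {"chrom": t.chrom, "pos": t.positions, "allele": allele, "lor": t.lor}
                )
            )
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "allele", "lor"])
        return pd.concat(frames, ignore_index=True)

    # -- reporting --------------------------------------------------------

    def qc(self) -> dict:
        return {
            "foetal_fraction": self.ff.ff,
            "ff_n_sites": self.ff.n_sites_used,
            "ff_out_of_clinical_range": bool(self.ff.out_of_clinical_range),
            "informative_counts": dict(self.informative.counts),
            "phase": {
                p: {
                    "n_candidates": ph.n_candidates,
                    "n_phased": ph.n_phased,
                    "n_conflicts": ph.n_conflicts,
                    "conflict_rate": ph.conflict_rate,
                }
                for p, ph in self.phased.items()
            },
            "n_crossovers": len(self.crossovers()),
        }

    def to_report(self) -> dict:
        return {
            "prediction": self.prediction.to_dict(),
            "qc": self.qc(),
            "parameters": {
                "epsilon": self.model.epsilon,
                "morgans_per_mb": self.model.transition.morgans_per_mb,
                "flank_bp": self.model.flank_bp,
                "min_snps": self.model.min_snps,
                "lor_threshold": self.model.lor_threshold,
                "ff_supplied": self.model.ff is not None,
            },
            "crossovers": [
                {
                    "parent": t.parent,
                    "chrom": co.chrom,
                    "start": co.start,
                    "end": co.end,
                    "midpoint": co.midpoint,
                    "transition": f"{co.from_state}>{co.to_state}",
                }
                for t in self.tracks
                for co in t.crossovers
            ],
        }

    def summary(self) -> str:
        """A human-readable fit summary."""
        r = self.model.rearrangement
        ped = self.model.pedigree
        lines = []
        bar = "=" * 72
        lines.append(bar)
        lines.append("Foetal haplotype transmission model".center(72))
        lines.append(bar)
        lines.append(f"Rearrangement:     {r.kind} (carrier: {r.carrier_parent})")
        for bp in r.breakpoints:
            lines.append(f"  breakpoint {bp.id}:  {bp.chrom}:{bp.start}-{bp.end}")
        lines.append(
            f"Reference:         {ped.reference_role} ({ped.reference_carrier_status})"
        )
        src = "supplied" if self.model.ff is not None else f"estimated, {self.ff.n_sites_used} sites"
        flag = "  [outside clinical range]" if self.ff.out_of_clinical_range else ""
        lines.append(f"Foetal fraction:   {self.ff.ff:.3f} ({src}){flag}")
        counts = self.informative.counts
        lines.append(
            "Informative SNPs:  "
            f"maternal {counts.get('maternal_informative', 0)}, "
            f"paternal {counts.get('paternal_informative', 0)}"
        )
        for p, ph in self.phased.items():
            lines.append(
                f"Phasing ({p}):  {ph.n_phased}/{ph.n_candidates} het SNPs phased, "
                f"{ph.n_conflicts} Mendelian conflicts"
            )
        lines.append("-" * 72)
        lines.append("Breakpoint windows:")
        for w in self.window_calls:
            lor = f"{w.mean_lor:+.2f}" if np.isfinite(w.mean_lor) else "NA"
            extra = f"  ({w.reason})" if w.reason else ""
            lines.append(
                f"  {w.breakpoint_id}  {w.chrom}:{w.window[0]}-{w.window[1]}  "
                f"n={w.n_informative_snps}  mean LOR={lor}  call={w.call}{extra}"
            )
        ncos = len(self.crossovers())
        lines.append(f"Crossovers detected: {ncos}")
        lines.append("-" * 72)
        lines.append(f"Predicted foetal karyotype: {self.prediction.call}")
        lines.append(bar)
        return "\n".join(lines)

    def plot_lor(self, chrom: str | None = None, ax=None, log10: bool = True):
        """Plot the posterior LOR track(s) with breakpoint windows shaded."""
        import matplotlib.pyplot as plt

        carrier = self.model.rearrangement.carrier_parent
        chroms = [chrom] if chrom else self.model.rearrangement.chromosomes
        if ax is None:
            _, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.6 * len(chroms)),
                                   squeeze=False)
            axes = [a for row in axes for a in row]
        else:
            axes = [ax]
        for a, c in zip(axes, chroms):
            t = self.track(carrier, c)
            if t is None:
                continue
            y = t.lor_log10 if log10 else t.lor
            a.plot(t.positions / 1e6, y, lw=0.8, color="0.2")
            a.axhline(0, color="0.6", lw=0.6)
            for w in self.window_calls:
                if w.chrom == c:
                    a.axvspan(w.window[0] / 1e6, w.window[1] / 1e6,
                              color="tab:orange", alpha=0.2)
            a.set_xlabel(f"{c} position (Mb)")
            a.set_ylabel("log10 odds Hap0:Hap1" if log10 else "ln odds Hap0:Hap1")
        return axes[0].figure
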
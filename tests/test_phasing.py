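"""Informative-SNP classification and family-based phasing."""

import numpy as np
import pytest

from conftest import make_genotypes
from niptsr.families import Breakpoint, Pedigree, Rearrangement
from niptsr.phasing import (
    MATERNAL,
    PATERNAL,
    PHASE_ONLY,
    UNINFORMATIVE,
    LabelingError,
    PhasingError,
    classify_informative,
    label_hap0,
    phase_parent,
)
from niptsr.simulate import SimConfig, simulate_family


class TestClassifyInformative:
    def test_classification_rules(self, grandparent_pedigree):
        # rows: (mother, father, reference) -> expected class
        cases = [
            ((1, 0, 0), MATERNAL),   # mother het, father hom
            ((1, 2, 0), MATERNAL),
            ((0, 1, 0), PATERNAL),   # father het, mother hom
            ((2, 1, 1), PATERNAL),
            ((0, 0, 0), UNINFORMATIVE),  # homozygous mother carries no signal
            ((2, 2, 1), UNINFORMATIVE),
            ((1, 1, 0), PHASE_ONLY),     # both het, reference resolves phase
            ((1, 1, 1), UNINFORMATIVE),
            ((-1, 0, 0), UNINFORMATIVE),  # missing genotype
        ]
        gts = make_genotypes(*zip(*[c[0] for c in cases]))
        res = classify_informative(gts, grandparent_pedigree)
        assert res.df["klass"].tolist() == [c[1] for c in cases]
        assert res.counts[MATERNAL] == 2
        assert res.counts[PATERNAL] == 2

    def test_counts_invariant_to_order(self, grandparent_pedigree):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 3, 50)
        f = rng.integers(0, 3, 50)
        r = rng.integers(0, 3, 50)
        a = classify_informative(make_genotypes(m, f, r), grandparent_pedigree)
        perm = rng.permutation(50)
        b = classify_informative(make_genotypes(m[perm], f[perm], r[perm]),
                                 grandparent_pedigree)
        assert a.counts == b.counts


def _one_chrom_rearr(carrier="mother"):
    return Rearrangement(
        kind="inversion",
        breakpoints=(Breakpoint("bp1", "chr1", 100, 150),
                     Breakpoint("bp2", "chr1", 500, 550)),
        carrier_parent=carrier,
    )


class TestPhaseParent:
    def test_grandparent_homozygous_resolves_phase(self, grandparent_pedigree):
        # mother ref/alt with grandmother alt/alt: the alt sits on the
        # grandmother-derived haplotype; het grandmother leaves the SNP unphased
        gts = make_genotypes([1, 1, 1], [0, 0, 0], [2, 0, 1])
        ph = phase_parent(gts, grandparent_pedigree, _one_chrom_rearr())
        assert ph.df["a1"].tolist() == [1, 0, -1]
        assert ph.df["a2"].tolist() == [0, 1, -1]
        assert ph.n_phased == 2

    def test_grandparent_cannot_phase_noncarrier(self, grandparent_pedigree):
        gts = make_genotypes([1, 1, 1], [1, 1, 1], [0, 0, 0])
        with pytest.raises(PhasingError):
            phase_parent(gts, grandparent_pedigree, _one_chrom_rearr(), parent="father")

    def test_child_route_transmitted_allele(self, child_pedigree):
        # mother het, father ref/ref, child carries an alt -> mother sent alt
        gts = make_genotypes(
            mother=[1, 1, 1, 1],
            father=[0, 0, 1, 1],
            reference=[1, 0, 2, 1],
        )
        ph = phase_parent(gts, child_pedigree, _one_chrom_rearr())
        # site0: alt transmitted; site1: ref; site2: child hom alt -> alt;
        # site3: both het and child het -> ambiguous, left unphased
        assert ph.df["a1"].tolist() == [1, 0, 1, -1]

    def test_mendelian_conflict_dropped_and_counted(self, child_pedigree):
        # father alt/alt contributes an obligate alt, child ref/ref impossible
        gts = make_genotypes([1, 1], [2, 0], [0, 1])
        ph = phase_parent(gts, child_pedigree, _one_chrom_rearr())
        assert ph.n_conflicts == 1
        assert ph.df["a1"].tolist() == [-1, 1]

    def test_unphased_flank_is_fatal(self, grandparent_pedigree):
        # grandmother heterozygous everywhere: nothing phases
        gts = make_genotypes([1, 1, 1], [0, 0, 0], [1, 1, 1])
        with pytest.raises(PhasingError):
            phase_parent(gts, grandparent_pedigree, _one_chrom_rearr())

    def test_hap_alleles_sum_to_genotype(self, grandparent_pedigree):
        rng = np.random.default_rng(4)
        m = rng.integers(0, 3, 200)
        m[:20] = 1  # ensure phased SNPs near the breakpoints
        r = rng.integers(0, 3, 200)
        r[:20] = (r[:20] // 2) * 2
        gts = make_genotypes(m, np.zeros(200, int), r, spacing=10)
        ph = phase_parent(gts, grandparent_pedigree, _one_chrom_rearr())
        mask = ph.phased_mask()
        a1 = ph.df["a1"].to_numpy()[mask]
        a2 = ph.df["a2"].to_numpy()[mask]
        assert ((a1 + a2) == m[mask]).all()


class TestLabelHap0:
    def test_carrier_reference_concordant_is_hap0(self, grandparent_pedigree):
        gts = make_genotypes([1, 1, 1], [0, 0, 0], [2, 0, 0])
        rearr = _one_chrom_rearr()
        ph = label_hap0(phase_parent(gts, grandparent_pedigree, rearr),
                        grandparent_pedigree, rearr)
        assert ph.hap0_side == {"chr1": "a1"}
        h0, h1 = ph.hap_alleles("chr1")
        assert h0.tolist() == [1, 0, 0]

    def test_noncarrier_reference_concordant_is_hap1(self):
        ped = Pedigree("M", "F", "GF", "grandparent", "non_carrier")
        gts = make_genotypes([1, 1, 1], [0, 0, 0], [2, 0, 0])
        rearr = _one_chrom_rearr()
        ph = label_hap0(phase_parent(gts, ped, rearr), ped, rearr)
        assert ph.hap0_side == {"chr1": "a2"}
        h0, _ = ph.hap_alleles("chr1")
        assert h0.tolist() == [0, 1, 1]  # complement of the reference haplotype

    def test_carrier_child_transmitted_is_hap0(self, child_pedigree):
        gts = make_genotypes([1, 1, 1], [0, 0, 0], [1, 1, 0])
        rearr = _one_chrom_rearr()
        ph = label_hap0(phase_parent(gts, child_pedigree, rearr),
                        child_pedigree, rearr)
        assert ph.hap0_side == {"chr1": "a1"}

    def test_missing_status_is_fatal(self):
        ped = Pedigree("M", "F", "GM", "grandparent", None)
        gts = make_genotypes([1, 1, 1], [0, 0, 0], [2, 0, 0])
        rearr = _one_chrom_rearr()
        with pytest.raises(LabelingError):
            label_hap0(phase_parent(gts, ped, rearr), ped, rearr)

    def test_labels_only_on_carrier_parent(self, child_pedigree):
        gts = make_genotypes([0, 0, 0], [1, 1, 1], [0, 1, 0])
        rearr = _one_chrom_rearr(carrier="mother")
        ph = phase_parent(gts, child_pedigree, rearr, parent="father")
        with pytest.raises(LabelingError):
            label_hap0(ph, child_pedigree, rearr)


class TestRoundTripWithSimulator:
    @pytest.mark.parametrize("status", ["carrier", "non_carrier"])
    def test_grandparent_phasing_recovers_truth(self, status):
        cfg = SimConfig(seed=21, reference_carrier_status=status)
        truth = simulate_family(cfg)
        ph = phase_parent(truth.genotypes, truth.pedigree, truth.rearrangement)
        ph = label_hap0(ph, truth.pedigree, truth.rearrangement)
        carrier_haps = truth.parent_haps(truth.rearrangement.carrier_parent)
        hap0_true = carrier_haps[truth.hap0_index]
        mask = ph.phased_mask()
        assert mask.sum() > 500
        assert ph.n_conflicts == 0
        for chrom in truth.panel.chromosomes:
            idx = truth.panel.chrom_index(chrom)
            h0, h1 = ph.hap_alleles(chrom)
            sel = mask[idx]
            # every phase-resolvable SNP matches the simulated Hap0 haplotype
            assert (h0[sel] == hap0_true[idx][sel]).all()
            assert (h1[sel] == carrier_haps[1 - truth.hap0_index][idx][sel]).all()
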
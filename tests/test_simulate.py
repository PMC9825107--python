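"""Simulator contracts: determinism, Mendelian consistency, meiosis and plasma."""

import numpy as np
import pandas as pd
import pytest

from niptsr.panel import Panel, spacing_stats
from niptsr.plasma import emission_theta
from niptsr.simulate import (
    GENOME_PANEL_SIZE,
    SimConfig,
    _meiosis,
    genome_panel,
    simulate_family,
    simulate_plasma,
)


class TestDeterminism:
    def test_same_seed_is_identical(self):
        a = simulate_family(SimConfig(seed=31))
        b = simulate_family(SimConfig(seed=31))
        assert a.genotypes.df.equals(b.genotypes.df)
        assert (a.mother_haps == b.mother_haps).all()
        assert a.crossovers == b.crossovers
        assert a.karyotype == b.karyotype
        pa = simulate_plasma(a)
        pb = simulate_plasma(b)
        assert pa.df.equals(pb.df)

    def test_different_seed_differs(self):
        a = simulate_family(SimConfig(seed=31))
        b = simulate_family(SimConfig(seed=32))
        assert not (a.mother_haps == b.mother_haps).all()


class TestMendelianConsistency:
    @pytest.mark.parametrize("role", ["grandparent", "sibling"])
    def test_foetus_and_reference_are_consistent(self, role):
        cfg = SimConfig(
            seed=33, reference_role=role,
            reference_carrier_status="carrier" if role == "grandparent" else "auto",
        )
        truth = simulate_family(cfg)
        m = truth.genotypes.dosages("mother")
        f = truth.genotypes.dosages("father")
        c = truth.foetal_genotype
        # the foetal genotype decomposes into one allele from each parent
        ma = truth.transmitted_alleles("mother")
        fa = truth.transmitted_alleles("father")
        assert (c == ma + fa).all()
        # each transmitted allele exists in that parent's genotype
        assert ((m == 1) | (ma == m // 2)).all()
        assert ((f == 1) | (fa == f // 2)).all()
        if role == "sibling":
            r = truth.genotypes.dosages("reference")
            # reference child also Mendelian-consistent with the couple
            assert (r >= (m // 2) * (m == 2) + (f // 2) * (f == 2)).all()
            assert (r <= 2 - ((m == 0) + (f == 0))).all()

    def test_karyotype_label_matches_transmission(self):
        truth = simulate_family(SimConfig(seed=34))
        rearr = truth.rearrangement
        carrier = rearr.carrier_parent
        sides = []
        for bp in rearr.breakpoints:
            idx = truth.panel.chrom_index(bp.chrom)
            pos = truth.panel.df["pos"].to_numpy()[idx]
            nearest = idx[np.argmin(np.abs(pos - bp.midpoint))]
            sides.append(truth.transmitted[carrier][nearest])
        want = {
            (True, True): "balanced_carrier",
            (False, False): "normal",
        }.get((sides[0] == truth.hap0_index, sides[1] == truth.hap0_index),
              "possible_unbalanced")
        assert truth.karyotype == want


class TestMeiosis:
    def test_poisson_crossover_mean(self):
        # 0.01 Morgans/Mb over 100 Mb -> one expected crossover per meiosis
        rng = np.random.default_rng(35)
        panel = Panel(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": np.arange(50) * 2_000_000,
                    "ref": "A",
                    "alt": "G",
                    "maf": 0.4,
                }
            )
        )
        counts = []
        for _ in range(2000):
            _, xs, _ = _meiosis(rng, panel, 0.01, chrom_lengths={"chr1": 100_000_000})
            counts.append(len(xs["chr1"]))
        assert np.mean(counts) == pytest.approx(1.0, abs=0.07)  # 3 s.e.

    def test_forced_crossovers_pin_positions(self):
        cfg = SimConfig(
            seed=36,
            forced_crossovers={("mother", "chr1"): [42e6], ("mother", "chr2"): []},
        )
        truth = simulate_family(cfg)
        assert truth.crossovers[("mother", "chr1")] == [42e6]
        assert truth.crossovers[("mother", "chr2")] == []
        ind = truth.transmitted["mother"]
        idx = truth.panel.chrom_index("chr1")
        pos = truth.panel.df["pos"].to_numpy()[idx]
        flips = np.flatnonzero(np.diff(ind[idx]) != 0)
        assert len(flips) == 1
        assert pos[flips[0]] < 42e6 <= pos[flips[0] + 1]


class TestSimulatePlasma:
    def test_pure_maternal_mixture_without_alt_source(self):
        # mother ref/ref and foetus ref/ref with no error: zero alt reads
        cfg = SimConfig(seed=37, epsilon=0.0)
        truth = simulate_family(cfg)
        plasma = simulate_plasma(truth)
        sel = (truth.genotypes.dosages("mother") == 0) & (truth.foetal_genotype == 0)
        assert sel.sum() > 50
        assert (plasma.alt_counts()[sel] == 0).all()

    def test_counts_match_emission_expectation(self):
        # law of large numbers at maternal-informative sites across a big panel
        cfg = SimConfig(
            seed=38,
            chromosomes={"chr1": 250_000_000, "chr2": 250_000_000},
            breakpoints=[("bp1", "chr1", 60e6, 60.01e6), ("bp2", "chr2", 30e6, 30.01e6)],
        )
        truth = simulate_family(cfg)
        plasma = simulate_plasma(truth)
        m = truth.genotypes.dosages("mother")
        theta = emission_theta(m, truth.foetal_genotype, cfg.ff, cfg.epsilon)
        sel = (m == 1) & (truth.foetal_genotype == 1)
        assert sel.sum() > 1000
        depth_tot = plasma.depths()[sel].sum()
        frac = plasma.alt_counts()[sel].sum() / depth_tot
        th = float(np.mean(theta[sel]))
        se = np.sqrt(th * (1 - th) / depth_tot)
        assert abs(frac - th) < 3 * se


class TestPanelFixtures:
    def test_desk_panel_density_and_maf(self):
        truth = simulate_family(SimConfig(seed=39))
        assert len(truth.panel) == pytest.approx(2 * 2170, rel=0.02)
        assert (truth.panel.df["maf"] > 0.3).all()
        st = spacing_stats(truth.panel)
        assert 30_000 < st.median_bp < 55_000

    def test_genome_panel_conformance(self):
        panel = genome_panel(seed=2)
        assert len(panel) == GENOME_PANEL_SIZE
        assert len(panel.chromosomes) == 22
        assert (panel.df["maf"] > 0.3).all()
        st = spacing_stats(panel)
        assert abs(st.median_bp - 40_000) < 4_000  # within 10 percent

    def test_breakpoint_off_genome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(breakpoints=[("bp1", "chr1", 60e6, 60.01e6),
                                   ("bp2", "chr2", 990e6, 991e6)])
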
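"""Truth-based evaluation helpers for simulated cases."""

from __future__ import annotations

import numpy as np

from .model import TransmissionResults
from .simulate import TruthSet

__all__ = [
    "allele_accuracy",
    "crossover_errors",
    "run_simulated_case",
    "accuracy_study",
    "crossover_localization_study",
]


def allele_accuracy(results: TransmissionResults, truth: TruthSet) -> dict:
    """Fraction of usable informative SNPs with a correct transmitted allele.

    Compares the marginal-MAP inferred transmitted allele of every
    inferred chain against the allele the simulated foetus actually
    inherited from that parent.  Returns per-parent and overall
    accuracies with counts.
    """
    per_parent = {}
    total_correct = 0
    total_n = 0
    for parent in results.phased:
        truth_alleles = truth.transmitted_alleles(parent)
        correct = 0
        n = 0
        for track in results.tracks:
            if track.parent != parent or track.panel_index is None:
                continue
            ph = results.phased[parent]
            h_first, h_second = results.model._oriented_haps(ph)
            states = track.map_states()
            inferred = np.where(
                states == 0, h_first[track.panel_index], h_second[track.panel_index]
            )
            correct += int((inferred == truth_alleles[track.panel_index]).sum())
            n += len(track)
        if n:
            per_parent[parent] = {"accuracy": correct / n, "n_snps": n}
            total_correct += correct
            total_n += n
    return {
        "overall": total_correct / total_n if total_n else float("nan"),
        "n_snps": total_n,
        "per_parent": per_parent,
    }


def crossover_errors(results: TransmissionResults, truth: TruthSet,
                     parent: str, chrom: str) -> list[float]:
    """Absolute localisation error of each true switch point, in bp.

    True switch points are the foetal crossovers (plus reference-phase
    switches when the reference is an offspring); each is matched to the
    nearest inferred crossover midpoint on the same chain.
    """
    track = results.track(parent, chrom)
    true_pts = truth.expected_switch_points(parent, chrom)
    if track is None or not true_pts:
        return []
    mids = np.array([co.midpoint for co in track.crossovers])
    if len(mids) == 0:
        return [float("inf")] * len(true_pts)
    return [float(np.min(np.abs(mids - p))) for p in true_pts]


def accuracy_study(
    family_seeds,
    mean_depth: float = 100.0,
    epsilon: float = 0.0011,
    ff_range: tuple[float, float] = (0.05, 0.30),
    reference_role: str = "sibling",
) -> dict:
    """Transmitted-allele accuracy over a batch of simulated families.

    Each family uses the desk-scale scenario (two 100-Mb chromosomes at
    genome-panel SNP density) with its foetal fraction drawn uniformly
    from ``ff_range`` and the carrier parent alternating between
    families.  The reference defaults to an existing child of the couple
    ("sibling"), which phases both parents so that maternal- and
    paternal-informative SNPs are both scored.  The true foetal fraction
    is passed to the model so the measurement isolates haplotype
    inference.  Returns the mean per-family accuracy and totals.
    """
    from .simulate import SimConfig

    per_family = []
    n_total = 0
    for k, seed in enumerate(family_seeds):
        ff = float(np.random.default_rng([int(seed), 2]).uniform(*ff_range))
        cfg = SimConfig(
            seed=int(seed),
            ff=ff,
            mean_depth=mean_depth,
            epsilon=epsilon,
            reference_role=reference_role,
            reference_carrier_status=(
                "carrier" if reference_role == "grandparent" else "auto"
            ),
            carrier_parent="mother" if k % 2 == 0 else "father",
        )
        truth, results = run_simulated_case(cfg, ff=ff)
        acc = allele_accuracy(results, truth)
        per_family.append(acc["overall"])
        n_total += acc["n_snps"]
    return {
        "mean_accuracy": float(np.mean(per_family)),
        "per_family": per_family,
        "n_families": len(per_family),
        "n_snps_total": n_total,
    }


def crossover_localization_study(
    n_meioses: int = 200,
    seed: int = 42,
    ff: float = 0.15,
    mean_depth: float = 100.0,
    edge_margin_bp: float = 10e6,
) -> np.ndarray:
    """Localisation error of a single forced maternal crossover.

    Each simulated meiosis places one crossover uniformly on chr1 at
    least ``edge_margin_bp`` from either end (no other crossovers in the
    foetal meioses); the error is the distance from the true position to
    the nearest inferred crossover midpoint on the maternal chr1 chain.
    Returns the per-meiosis absolute errors in bp.
    """
    from .simulate import SimConfig

    rng = np.random.default_rng(seed)
    length = 100_000_000
    errors = []
    for i in range(n_meioses):
        x = float(rng.uniform(edge_margin_bp, length - edge_margin_bp))
        forced = {
            ("mother", "chr1"): [x],
            ("mother", "chr2"): [],
            ("father", "chr1"): [],
            ("father", "chr2"): [],
        }
        cfg = SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            ff=ff,
            mean_depth=mean_depth,
            forced_crossovers=forced,
        )
        truth, results = run_simulated_case(cfg, ff=ff)
        errs = crossover_errors(results, truth, "mother", "chr1")
        errors.append(errs[0] if errs else float("inf"))
    return np.asarray(errors)


def run_simulated_case(config, **model_kwargs):
    """Simulate a case and fit the model on it; returns (truth, results).

    ``model_kwargs`` are forwarded to :class:`~niptsr.model.TransmissionModel`
    (e.g. ``ff=...`` to bypass estimation).
    """
    from .model import TransmissionModel
    from .simulate import simulate_family, simulate_plasma

    truth = simulate_family(config)
    plasma = simulate_plasma(truth, config)
    model = TransmissionModel(
        truth.panel, truth.genotypes, plasma, truth.pedigree,
        truth.rearrangement, **model_kwargs,
    )
    return truth, model.fit()
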
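"""Reusable simulation experiments at the study's conditions.

Each function runs a self-contained, seeded experiment with the package's
own machinery and returns plain numbers.  They back the acceptance checks,
the analysis drivers, and are convenient for calibration work:

* type-I error of the single-locus and two-locus tests under null crosses;
* calibration of the two-locus statistic under *independent* single-locus
  viability selection at both loci (its defining design property);
* delta-method coverage when recovering a simulated homozygote viability;
* the backcross asymmetry: a jointly-lethal linked pair distorts
  nonrecombinant (female-F1) backcrosses at a distal assay marker while
  recombinant (male-F1) backcrosses stay near 1:1;
* exact chromosome-wide cosegregation through achiasmatic females.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .epistasis import joint_counts, two_locus_test
from .markers import (
    POP2,
    CrossDesign,
    CrossKind,
    MarkerDef,
    MarkerPanel,
    default_panel,
    marginal_counts,
)
from .segdist import gof_test, relative_viability
from .simulate import (
    SimConfig,
    ViabilityModel,
    simulate_backcross_panel,
    simulate_cross,
)


def _spawn_seeds(seed: int, n: int) -> List[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def two_marker_panel() -> MarkerPanel:
    """Two unlinked markers (one per chromosome)."""
    return MarkerPanel([MarkerDef("A", "1", 0.0), MarkerDef("B", "2", 0.0)])


def _f2_config(panel, n, seed, viability=None) -> SimConfig:
    return SimConfig(
        panel=panel,
        design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
        n_offspring=n,
        seed=seed,
        viability=viability or ViabilityModel(),
    )


def single_locus_type1(
    seed: int, n_reps: int = 2000, n: int = 400, alpha: float = 0.05
) -> Dict[str, float]:
    """Rejection rate of the 1:2:1 goodness-of-fit test under a null F2."""
    panel = MarkerPanel([MarkerDef("A", "1", 0.0)])
    rejections = 0
    for s in _spawn_seeds(seed, n_reps):
        table = simulate_cross(_f2_config(panel, n, s))
        res = gof_test(marginal_counts(table, "A"), (0.25, 0.5, 0.25))
        rejections += res.p_value < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "n": n, "alpha": alpha}


def two_locus_type1(
    seed: int,
    n_reps: int = 2000,
    n: int = 400,
    alpha: float = 0.05,
    viability: Optional[ViabilityModel] = None,
) -> Dict[str, float]:
    """Rejection rate of the two-locus test on unlinked loci in an F2.

    With ``viability`` applying selection *independently at each locus*, the
    joint genotype distribution remains the product of its (distorted)
    marginals, so a calibrated rate here is the statistic's central design
    property: single-locus distortion must not masquerade as epistasis.
    """
    panel = two_marker_panel()
    rejections = 0
    for s in _spawn_seeds(seed, n_reps):
        table = simulate_cross(_f2_config(panel, n, s, viability))
        res = two_locus_test(joint_counts(table, ("A", "B")))
        rejections += res.p_value < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "n": n, "alpha": alpha}


def selection_both_loci(w_hom2: float = 0.4) -> ViabilityModel:
    """Independent homozygote-viability selection at both scan loci.

    The default w = (1, 1, 0.4) produces pronounced marginal distortion
    while keeping every expected joint cell above ~5 at n = 500 (Cochran's
    guidance for the chi-square approximation).
    """
    w = (1.0, 1.0, w_hom2)
    return ViabilityModel(single_locus={"A": w, "B": w})


def viability_recovery(
    seed: int, n_seeds: int = 200, n: int = 1000, w_true: float = 0.2
) -> Dict[str, float]:
    """Delta-method coverage when recovering a simulated homozygote viability.

    Simulates w = (1, 1, w_true) at one locus and checks how often the
    relative-viability estimate falls within 3 SEs of the truth.
    """
    panel = MarkerPanel([MarkerDef("A", "1", 0.0)])
    vm = ViabilityModel(single_locus={"A": (1.0, 1.0, w_true)})
    covered = 0
    estimates = []
    for s in _spawn_seeds(seed, n_seeds):
        table = simulate_cross(_f2_config(panel, n, s, vm))
        rv = relative_viability(marginal_counts(table, "A"))
        estimates.append(rv.w_hom_p2)
        if rv.se_p2 is not None and abs(rv.w_hom_p2 - w_true) <= 3 * rv.se_p2:
            covered += 1
    return {
        "coverage": covered / n_seeds,
        "mean_estimate": float(np.mean(estimates)),
        "n_seeds": n_seeds,
        "n": n,
        "w_true": w_true,
    }


def backcross_contrast_panel() -> MarkerPanel:
    """Assay marker at 0 cM with a tightly linked lethal pair far distal.

    Mirrors the motivating geometry: a long chromosome carries incompatible
    factors well away from the assayed marker, so in recombinant (male F1)
    meiosis the assay marker decouples from the lethal combination, while
    achiasmatic (female F1) transmission keeps the whole chromosome intact.
    """
    return MarkerPanel(
        [
            MarkerDef("M", "3", 0.0),
            MarkerDef("Q1", "3", 150.0),
            MarkerDef("Q2", "3", 170.0),
        ]
    )


def jointly_lethal_viability() -> ViabilityModel:
    """Lethal only when homozygous P2 at both distal loci; neutral otherwise."""
    tab = np.ones((3, 3))
    tab[2, 2] = 0.0
    return ViabilityModel(epistatic=[(("Q1", "Q2"), tab)])


def backcross_asymmetry(
    seed: int,
    n_seeds: int = 100,
    n: int = 200,
    family_alpha: float = 0.05,
) -> Dict[str, float]:
    """The nonrecombinant-backcross distortion contrast, over seeds.

    For each seed, all eight backcross types are simulated under the
    jointly-lethal linked-pair model and the assay marker is tested against
    1:1 at the Bonferroni level for 8 crosses (0.00625 at family alpha 0.05).
    Success: both female-F1 crosses to the lethal-background (P2) side are
    significantly distorted AND both male-F1 crosses to that side are not.
    """
    panel = backcross_contrast_panel()
    vm = jointly_lethal_viability()
    alpha = family_alpha / 8
    success = 0
    female_sig = 0
    male_sig = 0
    for s in _spawn_seeds(seed, n_seeds):
        tables = simulate_backcross_panel(panel, n, s, viability=vm)
        sig = {}
        for label, table in tables.items():
            if not label.endswith(("SDm", "SDf")):
                continue  # only the recurrent-P2 crosses can express lethality
            design = table.design_of(0)
            res = gof_test(marginal_counts(table, "M"), design.expected_ratio())
            sig[label] = res.p_value < alpha
        females = [v for k, v in sig.items() if k.startswith("F1f")]
        males = [v for k, v in sig.items() if k.startswith("F1m")]
        female_sig += sum(females)
        male_sig += sum(males)
        if all(females) and not any(males):
            success += 1
    return {
        "success_rate": success / n_seeds,
        "female_sig_rate": female_sig / (2 * n_seeds),
        "male_sig_rate": male_sig / (2 * n_seeds),
        "n_seeds": n_seeds,
        "n": n,
        "alpha": alpha,
    }


def cosegregation_exact(seed: int, n: int = 200) -> bool:
    """All markers on a chromosome identical in female-F1 backcross progeny.

    With achiasmatic females, every maternally transmitted chromosome is one
    intact parental haplotype, so in a female-F1 backcross the genotype is
    constant along each chromosome.  Exact, not statistical.
    """
    panel = default_panel()
    config = SimConfig(
        panel=panel,
        design=CrossDesign(
            kind=CrossKind.BACKCROSS, f1_parent_sex="F", recurrent_population=POP2
        ),
        n_offspring=n,
        seed=seed,
    )
    table = simulate_cross(config)
    for chrom, idx in panel.chrom_indices().items():
        block = table.calls[:, idx]
        if not np.all(block == block[:, [0]]):
            return False
    return True
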
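"""Forward simulation of experimental hybrid crosses.

Emulates the statistical structure of an inter-population *T. californicus*
cross experiment: F1 x F1 intercrosses, all eight backcross types, and
two-generation backcross / intercross programs, with

* **sex-limited recombination** — females are achiasmatic, transmitting each
  chromosome intact, while male meiosis recombines under Haldane's map
  function (no interference);
* **viability selection** — per-locus relative fitnesses and epistatic
  fitness tables over marker tuples, applied by rejection sampling;
* **sex determination** — a fair coin by default, or a polygenic-threshold
  model so synthetic data can exhibit sex-genotype associations.

Marker transmission is sampled at marker resolution: under a no-interference
crossover process, recombination events in disjoint intervals are
independent, so the gamete's strand sequence along a chromosome is a Markov
chain with switch probability r_i = Haldane(d_i) between adjacent markers.
This is the exact marginal law of the Poisson breakpoint process observed at
the markers, and is fully vectorizable.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .markers import (
    META_COLUMNS,
    POP1,
    POP2,
    CrossDesign,
    CrossKind,
    GenotypeTable,
    MarkerPanel,
)

REJECTION_CAP_PER_OFFSPRING = 1000


def haldane_r(d_cM: float) -> float:
    """Recombination fraction from map distance under Haldane's function."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


@dataclass(frozen=True)
class RecombinationModel:
    """Map-function recombination, optionally attenuated in females.

    ``female_recombination`` scales female map distances: 0 (the default,
    matching achiasmatic female meiosis) transmits chromosomes intact; 1
    makes the sexes equivalent.
    """

    female_recombination: float = 0.0
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_recombination <= 1.0):
            raise ConfigError(
                f"female_recombination must be in [0, 1], "
                f"got {self.female_recombination}"
            )
        if self.map_function != "haldane":
            raise ConfigError(f"unsupported map function {self.map_function!r}")


@dataclass
class DiploidGenome:
    """Two population-of-origin haplotypes per chromosome.

    ``haplotypes[chrom]`` is a (2, m) 0/1 array (0 = P1 origin), row 0 the
    maternally inherited strand.  The genotype code at a marker is the sum of
    the two origin labels.
    """

    haplotypes: Dict[str, np.ndarray]
    sex: str = "F"
    maternal_population: str = POP1

    def calls(self, panel: MarkerPanel) -> np.ndarray:
        out = np.empty(panel.n_markers, dtype=np.int8)
        for chrom, idx in panel.chrom_indices().items():
            out[idx] = self.haplotypes[chrom].sum(axis=0)
        return out


def purebred_genome(panel: MarkerPanel, population: str, sex: str = "F") -> DiploidGenome:
    label = 0 if population == POP1 else 1
    haps = {
        c: np.full((2, n), label, dtype=np.int8)
        for c, n in panel.chrom_sizes().items()
    }
    return DiploidGenome(haps, sex=sex, maternal_population=population)


def f1_genome(
    panel: MarkerPanel, maternal_population: str, sex: str = "F"
) -> DiploidGenome:
    """An F1 hybrid: heterozygous at every marker, maternal strand first."""
    m_label = 0 if maternal_population == POP1 else 1
    haps = {}
    for c, n in panel.chrom_sizes().items():
        h = np.empty((2, n), dtype=np.int8)
        h[0] = m_label
        h[1] = 1 - m_label
        haps[c] = h
    return DiploidGenome(haps, sex=sex, maternal_population=maternal_population)


def _adjacent_r(panel: MarkerPanel, scale: float) -> Dict[str, np.ndarray]:
    out = {}
    for chrom in panel.chromosomes:
        pos = panel.positions(chrom)
        d = np.diff(pos) * scale
        out[chrom] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return out


def make_gametes(
    parent: DiploidGenome,
    panel: MarkerPanel,
    model: RecombinationModel,
    rng: np.random.Generator,
    n: int,
) -> Dict[str, np.ndarray]:
    """Draw ``n`` gametes; returns per-chromosome (n, m) origin-label arrays.

    The starting strand is uniform per chromosome; the strand switches
    between adjacent markers with the Haldane recombination fraction of
    their map separation (scaled by ``female_recombination`` for female
    parents).  With an effective fraction of 0 every gamete chromosome is an
    exact copy of one parental haplotype.
    """
    scale = model.female_recombination if parent.sex == "F" else 1.0
    r_adj = _adjacent_r(panel, scale)
    gametes: Dict[str, np.ndarray] = {}
    for chrom in panel.chromosomes:
        hap = parent.haplotypes[chrom]
        m = hap.shape[1]
        start = rng.integers(0, 2, size=n)
        if m > 1:
            switches = rng.random((n, m - 1)) < r_adj[chrom]
            strand = (start[:, None] + np.cumsum(
                np.concatenate([np.zeros((n, 1), dtype=int), switches], axis=1),
                axis=1,
            )) % 2
        else:
            strand = start[:, None]
        gametes[chrom] = hap[strand, np.arange(m)[None, :]]
    return gametes


def make_gamete(
    parent: DiploidGenome,
    panel: MarkerPanel,
    model: RecombinationModel,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """One gamete: per-chromosome length-m origin-label vectors."""
    return {c: g[0] for c, g in make_gametes(parent, panel, model, rng, 1).items()}


@dataclass
class ViabilityModel:
    """Relative fitnesses driving viability selection.

    ``single_locus`` maps marker id -> (w0, w1, w2) fitness of the
    (HOM_P1, HET, HOM_P2) classes; ``epistatic`` lists (marker tuple,
    fitness table of shape (3,)*k) entries.  Fitness components are
    normalized by their maximum on construction, so each lies in [0, 1] and
    an individual's survival probability is the product of its applicable
    components.
    """

    single_locus: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    epistatic: List[Tuple[Tuple[str, ...], np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm_single = {}
        for marker, w in self.single_locus.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (3,) or np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ConfigError(f"invalid fitness triple for {marker!r}: {w}")
            if w.max() <= 0:
                raise ConfigError(f"all-zero fitness at {marker!r}")
            norm_single[marker] = tuple(w / w.max())
        self.single_locus = norm_single
        norm_epi = []
        for markers, tab in self.epistatic:
            markers = tuple(markers)
            tab = np.asarray(tab, dtype=float)
            if tab.shape != (3,) * len(markers):
                raise ConfigError(
                    f"epistatic table for {markers} has shape {tab.shape}"
                )
            if np.any(tab < 0) or not np.all(np.isfinite(tab)) or tab.max() <= 0:
                raise ConfigError(f"invalid epistatic fitness table for {markers}")
            norm_epi.append((markers, tab / tab.max()))
        self.epistatic = norm_epi

    def survival(self, calls: np.ndarray, panel: MarkerPanel) -> np.ndarray:
        """Survival probability of each row of a (n, m) call matrix."""
        s = np.ones(calls.shape[0], dtype=float)
        for marker, w in self.single_locus.items():
            j = panel.index_of(marker)
            s *= np.asarray(w)[calls[:, j]]
        for markers, tab in self.epistatic:
            idx = tuple(calls[:, panel.index_of(m)] for m in markers)
            s *= tab[idx]
        return s


@dataclass(frozen=True)
class SexModel:
    """Offspring sex: a fair coin, or a polygenic-threshold model where
    P(female) = logistic(sum of effect_i * (P2-allele dosage at marker_i - 1)).
    """

    kind: str = "bernoulli_half"
    effects: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("bernoulli_half", "polygenic"):
            raise ConfigError(f"unknown sex model {self.kind!r}")

    def p_female(self, calls: np.ndarray, panel: MarkerPanel) -> np.ndarray:
        n = calls.shape[0]
        if self.kind == "bernoulli_half" or not self.effects:
            return np.full(n, 0.5)
        z = np.zeros(n, dtype=float)
        for marker, effect in self.effects:
            j = panel.index_of(marker)
            z += effect * (calls[:, j].astype(float) - 1.0)
        return 1.0 / (1.0 + np.exp(-z))


def assign_sex(
    genome_calls: np.ndarray,
    sex_model: SexModel,
    panel: MarkerPanel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vector of "F"/"M" for each row of a call matrix."""
    p = sex_model.p_female(np.atleast_2d(genome_calls), panel)
    return np.where(rng.random(len(p)) < p, "F", "M")


@dataclass
class SimConfig:
    """One simulated cross: design, brood size, models, mandatory seed.

    ``maternal_population`` is the mtDNA background carried down the
    maternal line (for an F2 intercross, the population of the F1 dam's
    mother; the default P2 mirrors the motivating study's primary
    SD-female-founded cross direction).
    """

    panel: MarkerPanel
    design: CrossDesign
    n_offspring: int
    seed: int
    recombination: RecombinationModel = field(default_factory=RecombinationModel)
    viability: ViabilityModel = field(default_factory=ViabilityModel)
    sex_model: SexModel = field(default_factory=SexModel)
    maternal_population: str = POP2
    cross_id: str = "sim"
    stage: str = "ADULT"
    temperature_C: Optional[float] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is required")
        if self.n_offspring < 0:
            raise ConfigError("n_offspring must be >= 0")
        if self.maternal_population not in (POP1, POP2):
            raise ConfigError(
                f"invalid maternal_population {self.maternal_population!r}"
            )


def _parents_for_design(config: SimConfig) -> Tuple[DiploidGenome, DiploidGenome]:
    design = config.design
    panel = config.panel
    if design.kind is CrossKind.F2_INTERCROSS:
        mother = f1_genome(panel, config.maternal_population, sex="F")
        father = f1_genome(panel, config.maternal_population, sex="M")
        return mother, father
    if design.kind is CrossKind.BACKCROSS:
        if design.f1_parent_sex == "F":
            mother = f1_genome(panel, config.maternal_population, sex="F")
            father = purebred_genome(panel, design.recurrent_population, sex="M")
        elif design.f1_parent_sex == "M":
            mother = purebred_genome(panel, design.recurrent_population, sex="F")
            father = f1_genome(panel, config.maternal_population, sex="M")
        else:
            raise ConfigError("BACKCROSS requires f1_parent_sex F or M")
        return mother, father
    raise ConfigError(
        "BC2_INTERCROSS designs are produced by simulate_bc2_intercross"
    )


def _offspring_batch(
    mother: DiploidGenome,
    father: DiploidGenome,
    panel: MarkerPanel,
    model: RecombinationModel,
    rng: np.random.Generator,
    n: int,
) -> Dict[str, np.ndarray]:
    """n candidate offspring as per-chromosome (n, 2, m) haplotype stacks."""
    mat = make_gametes(mother, panel, model, rng, n)
    pat = make_gametes(father, panel, model, rng, n)
    return {c: np.stack([mat[c], pat[c]], axis=1) for c in panel.chromosomes}


def _calls_from_batch(batch: Dict[str, np.ndarray], panel: MarkerPanel) -> np.ndarray:
    n = next(iter(batch.values())).shape[0]
    calls = np.empty((n, panel.n_markers), dtype=np.int8)
    for chrom, idx in panel.chrom_indices().items():
        calls[:, idx] = batch[chrom].sum(axis=1)
    return calls


def _rejection_sample(
    mother: DiploidGenome,
    father: DiploidGenome,
    panel: MarkerPanel,
    recombination: RecombinationModel,
    viability: ViabilityModel,
    rng: np.random.Generator,
    n: int,
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Draw n surviving offspring; returns (haplotype batch, call matrix)."""
    kept_batches: List[Dict[str, np.ndarray]] = []
    kept_calls: List[np.ndarray] = []
    accepted = 0
    candidates = 0
    cap = REJECTION_CAP_PER_OFFSPRING * max(n, 1)
    while accepted < n:
        b = int(min(max(2 * (n - accepted), 64), 20000))
        batch = _offspring_batch(mother, father, panel, recombination, rng, b)
        calls = _calls_from_batch(batch, panel)
        s = viability.survival(calls, panel)
        keep = rng.random(b) < s
        candidates += b
        if keep.any():
            kept_batches.append({c: h[keep] for c, h in batch.items()})
            kept_calls.append(calls[keep])
            accepted += int(keep.sum())
        if accepted < n and candidates >= cap:
            raise DataError(
                f"viability model rejected {candidates} candidates for "
                f"{accepted}/{n} survivors; model may be (near-)lethal for "
                "all genotypes this cross can produce"
            )
    if n == 0:
        empty = {
            c: np.empty((0, 2, m), dtype=np.int8)
            for c, m in panel.chrom_sizes().items()
        }
        return empty, np.empty((0, panel.n_markers), dtype=np.int8)
    batch = {
        c: np.concatenate([kb[c] for kb in kept_batches], axis=0)[:n]
        for c in panel.chromosomes
    }
    calls = np.concatenate(kept_calls, axis=0)[:n]
    return batch, calls


def _meta_frame(
    config: SimConfig, sexes: np.ndarray, maternal_population: str
) -> pd.DataFrame:
    n = len(sexes)
    return pd.DataFrame(
        {
            "individual_id": [f"{config.cross_id}_{i:05d}" for i in range(n)],
            "cross_id": config.cross_id,
            "design": config.design.kind.value,
            "f1_parent_sex": config.design.f1_parent_sex,
            "recurrent_population": config.design.recurrent_population,
            "maternal_population": maternal_population,
            "sex": sexes,
            "stage": config.stage,
            "temperature_C": (
                np.nan if config.temperature_C is None else float(config.temperature_C)
            ),
        },
        columns=list(META_COLUMNS),
    )


def simulate_cross(config: SimConfig) -> GenotypeTable:
    """Simulate one cross, returning survivors' genotypes with metadata.

    Offspring are drawn by rejection sampling: one gamete from each parent,
    kept with probability equal to the candidate's viability.  The result is
    deterministic given the config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    mother, father = _parents_for_design(config)
    # the offspring's mtDNA background follows the maternal line
    if config.design.kind is CrossKind.BACKCROSS and config.design.f1_parent_sex == "M":
        maternal_pop = config.design.recurrent_population
    else:
        maternal_pop = config.maternal_population
    _, calls = _rejection_sample(
        mother, father, config.panel, config.recombination, config.viability,
        rng, config.n_offspring,
    )
    sexes = assign_sex(calls, config.sex_model, config.panel, rng)
    meta = _meta_frame(config, sexes, maternal_pop)
    return GenotypeTable(config.panel, meta, calls)


BACKCROSS_LABELS = [
    # (f1_origin maternal pop, f1 sex, recurrent pop)
    (POP2, "F", POP2), (POP2, "M", POP2),
    (POP1, "F", POP2), (POP1, "M", POP2),
    (POP2, "F", POP1), (POP2, "M", POP1),
    (POP1, "F", POP1), (POP1, "M", POP1),
]


def backcross_label(
    f1_maternal: str, f1_sex: str, recurrent: str,
    p1_name: str = "AB", p2_name: str = "SD",
) -> str:
    """Table-style cross label, e.g. "F1f(DA)xSDm" for an F1 female from the
    SD-mother cross backcrossed to an SD male."""
    origin = "DA" if f1_maternal == POP2 else "AD"
    rec = p2_name if recurrent == POP2 else p1_name
    other_sex = "m" if f1_sex == "F" else "f"
    return f"F1{f1_sex.lower()}({origin})x{rec}{other_sex}"


def simulate_backcross_panel(
    panel: MarkerPanel,
    n_per_cross: int,
    seed: int,
    *,
    recombination: Optional[RecombinationModel] = None,
    viability: Optional[ViabilityModel] = None,
    sex_model: Optional[SexModel] = None,
) -> Dict[str, GenotypeTable]:
    """All eight backcross types: {DA, AD F1 origin} x {F1 female, male} x
    {recurrent P2, P1}, labeled in the study's Table-1 style."""
    recombination = recombination or RecombinationModel()
    viability = viability or ViabilityModel()
    sex_model = sex_model or SexModel()
    children = np.random.SeedSequence(seed).spawn(len(BACKCROSS_LABELS))
    out: Dict[str, GenotypeTable] = {}
    for (f1_mat, f1_sex, rec), child in zip(BACKCROSS_LABELS, children):
        label = backcross_label(f1_mat, f1_sex, rec)
        config = SimConfig(
            panel=panel,
            design=CrossDesign(
                kind=CrossKind.BACKCROSS,
                f1_parent_sex=f1_sex,
                recurrent_population=rec,
            ),
            n_offspring=n_per_cross,
            seed=int(child.generate_state(1)[0] % (2**31)),
            recombination=recombination,
            viability=viability,
            sex_model=sex_model,
            maternal_population=f1_mat,
            cross_id=label,
        )
        out[label] = simulate_cross(config)
    return out


@dataclass
class Bc2Line:
    """One het x het second-generation backcross line."""

    line_id: str
    mother_calls: np.ndarray  # parental genotype vectors over the panel
    father_calls: np.ndarray
    progeny: GenotypeTable


def _pick_individual(
    batch: Dict[str, np.ndarray],
    calls: np.ndarray,
    sexes: np.ndarray,
    want_sex: str,
    het_at: int,
    maternal_population: str,
) -> Optional[DiploidGenome]:
    ok = np.nonzero((sexes == want_sex) & (calls[:, het_at] == 1))[0]
    if len(ok) == 0:
        return None
    i = int(ok[0])
    haps = {c: batch[c][i].copy() for c in batch}
    return DiploidGenome(haps, sex=want_sex, maternal_population=maternal_population)


def simulate_bc2_intercross(
    panel: MarkerPanel,
    focal_marker: str,
    n_lines: int,
    n_progeny: int,
    seed: int,
    *,
    recurrent: str = POP1,
    recombination: Optional[RecombinationModel] = None,
    viability: Optional[ViabilityModel] = None,
    sex_model: Optional[SexModel] = None,
    brood_size: int = 40,
) -> Tuple[List[Bc2Line], int]:
    """Two-generation backcross program with genotype-based parent selection.

    Starting from an F1 hybrid female (DA direction by default), each line is
    backcrossed to recurrent-population males for two generations, at each
    step retaining only parents heterozygous at ``focal_marker`` (with no
    female recombination, such a parent is heterozygous across the entire
    focal chromosome).  Two retained second-generation individuals (one of
    each sex) are intercrossed; the line records both parents' full marker
    genotypes plus the progeny table.  Lines where no suitable parent exists
    are dropped; returns (lines, n_dropped).
    """
    recombination = recombination or RecombinationModel()
    viability = viability or ViabilityModel()
    sex_model = sex_model or SexModel()
    j_focal = panel.index_of(focal_marker)
    lines: List[Bc2Line] = []
    dropped = 0
    children = np.random.SeedSequence(seed).spawn(n_lines)
    for line_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        line_id = f"line{line_idx + 1}"
        mother = f1_genome(panel, maternal_population=POP2, sex="F")
        rec_father = purebred_genome(panel, recurrent, sex="M")
        # two generations of backcrossing, keeping a focal-het female
        ok = True
        for _gen in range(2):
            batch, calls = _rejection_sample(
                mother, rec_father, panel, recombination, viability, rng, brood_size
            )
            sexes = assign_sex(calls, sex_model, panel, rng)
            nxt = _pick_individual(
                batch, calls, sexes, "F", j_focal, mother.maternal_population
            )
            if nxt is None:
                ok = False
                break
            mother = nxt
        if not ok:
            dropped += 1
            continue
        # final brood from the BC2 female x recurrent male; intercross a
        # focal-het daughter with a focal-het son
        batch, calls = _rejection_sample(
            mother, rec_father, panel, recombination, viability, rng, brood_size
        )
        sexes = assign_sex(calls, sex_model, panel, rng)
        dam = _pick_individual(batch, calls, sexes, "F", j_focal, mother.maternal_population)
        sire = _pick_individual(batch, calls, sexes, "M", j_focal, mother.maternal_population)
        if dam is None or sire is None:
            dropped += 1
            continue
        config = SimConfig(
            panel=panel,
            design=CrossDesign(kind=CrossKind.BC2_INTERCROSS),
            n_offspring=n_progeny,
            seed=int(rng.integers(0, 2**31)),
            recombination=recombination,
            viability=viability,
            sex_model=sex_model,
            maternal_population=dam.maternal_population,
            cross_id=line_id,
        )
        rng2 = np.random.default_rng(config.seed)
        _, pcalls = _rejection_sample(
            dam, sire, panel, recombination, viability, rng2, n_progeny
        )
        psex = assign_sex(pcalls, sex_model, panel, rng2)
        meta = _meta_frame(config, psex, dam.maternal_population)
        progeny = GenotypeTable(panel, meta, pcalls)
        lines.append(
            Bc2Line(
                line_id=line_id,
                mother_calls=dam.calls(panel),
                father_calls=sire.calls(panel),
                progeny=progeny,
            )
        )
    return lines, dropped
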
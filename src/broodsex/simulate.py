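"""Synthetic pedigrees and brood records under a liability-threshold model.

Sex is modelled as a threshold trait: offspring i has an unobserved
liability

    l_i = mu + a_i + m_dam(i) + e_i,      e_i ~ N(0, 1),

and is male iff l_i > 0.  Breeding values follow the infinitesimal model:
a_i = (a_sire + a_dam)/2 + Mendelian deviate with variance
sigma2_a * d_i, d_i = 1/2 - (F_sire + F_dam)/4, and each dam carries a
single maternal deviate m ~ N(0, sigma2_m) shared by all her offspring.

The generators emulate the study design this package analyses: two
truncation-selected lines diverging in brood sex ratio, an incomplete
diallel F1 design (2 blocks x [4 female-biased + 4 male-biased families],
within block, no within-family crosses, reciprocals distinct) and
backcrosses of the between-line F1 families to both selection lines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .broods import BroodRecord, broods_to_frame
from .pedigree import PedigreeRecord, PedigreeTable, validate_and_sort

__all__ = [
    "GeneticConfig",
    "SelectionConfig",
    "CrossDesign",
    "BroodSizeDistribution",
    "CrossPlan",
    "SimulatedDataset",
    "SelectionResult",
    "SimPopulation",
    "enumerate_f1_design",
    "enumerate_backcross_design",
    "simulate_broods",
    "simulate_truncation_selection",
    "simulate_diallel_dataset",
    "random_pedigree",
]


@dataclass(frozen=True)
class GeneticConfig:
    """Liability-scale variance components.

    The threshold is fixed at 0 and the residual variance at 1 (the usual
    identifiability constraints for a probit threshold trait); ``mu`` is the
    liability intercept.  Latent-scale heritability implied by a config is
    ``sigma2_a / (sigma2_a + sigma2_m + 1)``.
    """

    sigma2_a: float = 0.35
    sigma2_m: float = 0.05
    mu: float = 0.0
    threshold: float = 0.0
    residual_variance: float = 1.0

    def __post_init__(self):
        if self.sigma2_a < 0 or self.sigma2_m < 0:
            raise ValueError("invalid config: variances must be non-negative")
        if self.residual_variance != 1.0:
            raise ValueError("invalid config: residual variance is fixed at 1")

    @property
    def h2_latent(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_m + 1.0)


@dataclass(frozen=True)
class BroodSizeDistribution:
    """Shifted negative binomial brood sizes.

    ``size = shift + NegBin(mean - shift, dispersion)``, optionally resampled
    until ``size >= minimum``.  The default (mean ~30, mild overdispersion,
    no lower truncation) produces a small fraction of broods below the
    usual >11-offspring analysis filter, as observed brood data do.
    """

    mean: float = 30.0
    dispersion: float = 8.0
    shift: int = 1
    minimum: int = 1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        m = self.mean - self.shift
        k = self.dispersion
        p = k / (k + m)
        out = self.shift + rng.negative_binomial(k, p, size=size)
        bad = out < self.minimum
        while bad.any():
            out[bad] = self.shift + rng.negative_binomial(k, p, size=int(bad.sum()))
            bad = out < self.minimum
        return out


@dataclass(frozen=True)
class SelectionConfig:
    """Truncation-selection regime for one line."""

    n_generations: int = 6
    n_families_screened: int = 56
    n_selected: int = 8
    direction: str = "male-biased"  # male-biased | female-biased | control
    brood_sizes: BroodSizeDistribution = field(default_factory=BroodSizeDistribution)

    def __post_init__(self):
        if self.n_selected > self.n_families_screened:
            raise ValueError("n_selected must be <= n_families_screened")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.direction not in ("male-biased", "female-biased", "control"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CrossDesign:
    """Incomplete diallel F1 design among selected-line families."""

    n_blocks: int = 2
    families_per_line_per_block: int = 4
    reciprocal: bool = True
    within_family_allowed: bool = False
    within_block_only: bool = True


@dataclass(frozen=True)
class F1Cross:
    dam_family: str
    sire_family: str
    cross_type: str  # FF / FM / MF / MM (dam letter first)
    block: int


@dataclass(frozen=True)
class CrossPlan:
    """One planned mating between two named individuals."""

    cross_id: str
    dam: str
    sire: str
    block: int = 1
    cross_type: str = "other"
    generation: int = 1


def enumerate_f1_design(design: CrossDesign) -> list[F1Cross]:
    """All dam x sire family pairs of the incomplete diallel.

    Per block: FF and MM are ordered within-line pairs (same-family pairs
    excluded unless ``within_family_allowed``), FM and MF all ordered
    cross-line pairs; reciprocals are distinct crosses.  With the default
    2 blocks x (4+4) families this yields 12 FF + 12 MM + 16 FM + 16 MF
    = 56 crosses per block, 112 in total.
    """
    k = design.families_per_line_per_block
    out: list[F1Cross] = []
    blocks = range(1, design.n_blocks + 1)
    if not design.within_block_only:
        blocks = [0]
        k = k * design.n_blocks
    for b in blocks:
        fams = {
            "F": [f"B{b}-F{i}" for i in range(1, k + 1)],
            "M": [f"B{b}-M{i}" for i in range(1, k + 1)],
        }
        for dl, sl in (("F", "F"), ("F", "M"), ("M", "F"), ("M", "M")):
            pairs = itertools.product(fams[dl], fams[sl])
            for dam_f, sire_f in pairs:
                if dam_f == sire_f and not design.within_family_allowed:
                    continue
                if not design.reciprocal and dl != sl and (dl, sl) == ("M", "F"):
                    continue
                out.append(F1Cross(dam_f, sire_f, dl + sl, b))
    return out


def enumerate_backcross_design(
    f1_families: int, parent_families: int, reciprocal: bool = True
) -> tuple[int, list[tuple[int, int, str]]]:
    """Ordered (F1 family, selection-line family) backcross pairs.

    Each pair appears once with the F1 individual as dam and, when
    ``reciprocal``, once as sire; the count is
    ``f1_families * parent_families * (2 if reciprocal else 1)``.
    """
    if f1_families < 0 or parent_families < 0:
        raise ValueError("family counts must be non-negative")
    pairs = [
        (i, j, "f1_dam")
        for i in range(f1_families)
        for j in range(parent_families)
    ]
    if reciprocal:
        pairs += [(i, j, "f1_sire") for i, j in itertools.product(range(f1_families), range(parent_families))]
    return len(pairs), pairs


class SimPopulation:
    """Growing pedigree of simulated individuals with breeding values.

    Tracks, per individual: parent links, sex, generation, a line-source
    letter (F / M for pure-line ancestry, H for between-line hybrids) used
    to label parental origin, the breeding value, and the inbreeding
    coefficient (computed incrementally from pedigree kinship).
    """

    def __init__(self, gen: GeneticConfig):
        self.gen = gen
        self.ids: list[str] = []
        self.index: dict[str, int] = {}
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.sex: list[str] = []
        self.generation: list[int] = []
        self.source: list[str] = []
        self.line_origin: list[str] = []
        self.bv: list[float] = []
        self.F: list[float] = []
        self.block: list[int] = []
        self.parental_origin: list[str] = []
        self._maternal: dict[int, float] = {}
        self._kin: dict[tuple[int, int], float] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def _phi(self, i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        v = self._kin.get((i, j))
        if v is not None:
            return v
        if i == j:
            v = 0.5 * (1.0 + self._phi(self.sire[i], self.dam[i]))
        else:
            v = 0.5 * (self._phi(i, self.sire[j]) + self._phi(i, self.dam[j]))
        self._kin[(i, j)] = v
        return v

    def add_founder(
        self,
        id: str,
        sex: str,
        rng: np.random.Generator,
        mean_bv: float = 0.0,
        line: str = "other",
        block: int = 1,
        generation: int = 0,
    ) -> str:
        if id in self.index:
            raise ValueError(f"duplicate individual {id!r}")
        self.index[id] = len(self.ids)
        self.ids.append(id)
        self.sire.append(-1)
        self.dam.append(-1)
        self.sex.append(sex)
        self.generation.append(generation)
        self.source.append(line if line in ("F", "M") else "H")
        self.line_origin.append(line)
        self.bv.append(mean_bv + np.sqrt(self.gen.sigma2_a) * rng.standard_normal())
        self.F.append(0.0)
        self.block.append(block)
        self.parental_origin.append(line * 2 if line in ("F", "M") else "other")
        return id

    def maternal_deviate(self, dam_idx: int, rng: np.random.Generator) -> float:
        if dam_idx not in self._maternal:
            self._maternal[dam_idx] = np.sqrt(self.gen.sigma2_m) * rng.standard_normal()
        return self._maternal[dam_idx]

    def spawn_brood(
        self,
        dam: str,
        sire: str,
        size: int,
        rng: np.random.Generator,
        prefix: str,
        block: int = 1,
        generation: int = 1,
    ) -> list[str]:
        """Create ``size`` offspring of one mating; returns their ids."""
        di, si = self.index[dam], self.index[sire]
        if self.sex[si] == "female" or self.sex[di] == "male":
            raise ValueError("sex inconsistency in cross parents")
        f_child = self._phi(si, di)
        d_mend = 0.5 - 0.25 * (self.F[si] + self.F[di])
        mid = 0.5 * (self.bv[si] + self.bv[di])
        m_dev = self.maternal_deviate(di, rng)
        a = mid + np.sqrt(self.gen.sigma2_a * d_mend) * rng.standard_normal(size)
        liab = self.gen.mu + a + m_dev + rng.standard_normal(size)
        male = liab > self.gen.threshold
        src_d, src_s = self.source[di], self.source[si]
        child_source = src_d if (src_d == src_s and src_d in ("F", "M")) else "H"
        origin = src_d + src_s
        ids = []
        for k in range(size):
            cid = f"{prefix}-{k + 1}"
            self.index[cid] = len(self.ids)
            self.ids.append(cid)
            self.sire.append(si)
            self.dam.append(di)
            self.sex.append("male" if male[k] else "female")
            self.generation.append(generation)
            self.source.append(child_source)
            self.line_origin.append({"F": "F", "M": "M"}.get(child_source, "F1"))
            self.bv.append(float(a[k]))
            self.F.append(f_child)
            self.block.append(block)
            self.parental_origin.append(origin)
            ids.append(cid)
        return ids

    def members_of_sex(self, ids: Sequence[str], sex: str) -> list[str]:
        return [i for i in ids if self.sex[self.index[i]] == sex]

    def pedigree(self) -> PedigreeTable:
        recs = [
            PedigreeRecord(
                id=self.ids[i],
                sire=self.ids[self.sire[i]] if self.sire[i] >= 0 else None,
                dam=self.ids[self.dam[i]] if self.dam[i] >= 0 else None,
                sex=self.sex[i],
                generation=self.generation[i],
                line_origin=self.line_origin[i],
            )
            for i in range(len(self.ids))
        ]
        return validate_and_sort(recs)

    def phenotype_frame(self, include_founders: bool = False) -> pd.DataFrame:
        """Phenotyped individuals for the animal model.

        By default only brood offspring are included: founder sexes are
        design assignments, not draws from the liability model.
        """
        rows = []
        for i in range(len(self.ids)):
            if self.dam[i] < 0 and not include_founders:
                continue
            rows.append(
                {
                    "id": self.ids[i],
                    "sex": self.sex[i],
                    "block": self.block[i],
                    "parental_origin": self.parental_origin[i],
                    "dam": self.ids[self.dam[i]] if self.dam[i] >= 0 else None,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """A simulated pedigree + brood records with known generating values."""

    pedigree: PedigreeTable
    broods: list[BroodRecord]
    phenotypes: pd.DataFrame
    true_params: GeneticConfig
    seed: Optional[int]
    population: Optional[SimPopulation] = None

    def broods_frame(self) -> pd.DataFrame:
        return broods_to_frame(self.broods)


def simulate_broods(
    crosses: Iterable[CrossPlan],
    gen: GeneticConfig,
    brood_sizes: BroodSizeDistribution = BroodSizeDistribution(),
    seed: Optional[int] = None,
    population: Optional[SimPopulation] = None,
    broods_per_cross: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedDataset:
    """Simulate brood sex counts for a list of planned crosses.

    Parents named in ``crosses`` that are not already in ``population``
    are created as unrelated founders with breeding values drawn from
    N(0, sigma2_a).  Each cross produces ``broods_per_cross`` broods with
    sizes drawn from ``brood_sizes``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pop = population if population is not None else SimPopulation(gen)
    crosses = list(crosses)
    for c in crosses:
        if c.dam not in pop.index:
            pop.add_founder(c.dam, "female", rng, line="other", block=c.block)
        if c.sire not in pop.index:
            pop.add_founder(c.sire, "male", rng, line="other", block=c.block)
    records: list[BroodRecord] = []
    sizes = brood_sizes.sample(rng, len(crosses) * broods_per_cross)
    k = 0
    for c in crosses:
        for b in range(1, broods_per_cross + 1):
            ids = pop.spawn_brood(
                c.dam,
                c.sire,
                int(sizes[k]),
                rng,
                prefix=f"{c.cross_id}b{b}",
                block=c.block,
                generation=c.generation,
            )
            n_male = sum(pop.sex[pop.index[i]] == "male" for i in ids)
            records.append(
                BroodRecord(
                    cross_id=c.cross_id,
                    dam=c.dam,
                    sire=c.sire,
                    block=c.block,
                    cross_type=c.cross_type,
                    generation=c.generation,
                    n_male=n_male,
                    n_female=len(ids) - n_male,
                    brood_index=b,
                )
            )
            k += 1
    return SimulatedDataset(
        pedigree=pop.pedigree(),
        broods=records,
        phenotypes=pop.phenotype_frame(),
        true_params=gen,
        seed=seed,
        population=pop,
    )


@dataclass
class SelectionResult:
    """Per-generation response summaries of one truncation-selected line."""

    summaries: pd.DataFrame
    population: SimPopulation
    final_family_broods: list[list[str]]

    def pedigree(self) -> PedigreeTable:
        return self.population.pedigree()


def simulate_truncation_selection(
    sel: SelectionConfig,
    gen: GeneticConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SelectionResult:
    """Simulate generations of truncation selection on brood sex ratio.

    Each generation, ``n_families_screened`` single-pair families each
    produce one brood; families are ranked by brood sex ratio (most
    male-biased first for a male-biased line, most female-biased first for
    a female-biased line, random for a control) with ties broken by a
    seeded uniform jitter, and the top ``n_selected`` families supply the
    parents of the next generation (dam from one selected family, sire from
    another).  Raises "line extinction" if no parent pairs can be formed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pop = SimPopulation(gen)
    tag = {"male-biased": "M", "female-biased": "F", "control": "C"}[sel.direction]
    families: list[tuple[str, str]] = []
    for i in range(sel.n_families_screened):
        d = pop.add_founder(f"{tag}0d{i}", "female", rng, line="other")
        s = pop.add_founder(f"{tag}0s{i}", "male", rng, line="other")
        families.append((d, s))
    rows = []
    final_broods: list[list[str]] = []
    for g in range(1, sel.n_generations + 1):
        sizes = sel.brood_sizes.sample(rng, len(families))
        broods, bsrs = [], []
        for k, (d, s) in enumerate(families):
            ids = pop.spawn_brood(d, s, int(sizes[k]), rng, prefix=f"{tag}{g}f{k}", generation=g)
            broods.append(ids)
            n_male = sum(pop.sex[pop.index[i]] == "male" for i in ids)
            bsrs.append(n_male / len(ids))
        bsrs = np.asarray(bsrs)
        jitter = rng.uniform(0, 1e-9, size=len(bsrs))
        if sel.direction == "male-biased":
            order = np.argsort(-(bsrs + jitter), kind="stable")
        elif sel.direction == "female-biased":
            order = np.argsort(bsrs + jitter, kind="stable")
        else:
            order = rng.permutation(len(bsrs))
        chosen = order[: sel.n_selected]
        rows.append(
            {
                "generation": g,
                "mean_bsr_selected": float(bsrs[chosen].mean()),
                "sd_bsr_selected": float(bsrs[chosen].std(ddof=1)) if len(chosen) > 1 else np.nan,
                "mean_bsr_screened": float(bsrs.mean()),
                "sd_bsr_screened": float(bsrs.std(ddof=1)),
            }
        )
        final_broods = [broods[i] for i in chosen]
        if g == sel.n_generations:
            break
        # next generation: selection acts on females only — dams come from the
        # selected broods, sires from the line at large (a screened family is
        # picked uniformly, then a male within it, so male-biased families do
        # not dominate the sire pool simply by producing more sons)
        dams_by_fam = [pop.members_of_sex(b, "female") for b in final_broods]
        fam_with_dams = [i for i, v in enumerate(dams_by_fam) if v]
        sires_by_any_fam = [pop.members_of_sex(b, "male") for b in broods]
        any_with_sires = [k for k, v in enumerate(sires_by_any_fam) if v]
        if not fam_with_dams or not any_with_sires:
            raise RuntimeError("line extinction: no offspring of needed sex to breed")
        families = []
        for i in range(sel.n_families_screened):
            fd = fam_with_dams[i % len(fam_with_dams)]
            d = str(rng.choice(dams_by_fam[fd]))
            dam_orig = chosen[fd]
            fams = [k for k in any_with_sires if k != dam_orig] or any_with_sires
            fs = fams[int(rng.integers(len(fams)))]
            s = str(rng.choice(sires_by_any_fam[fs]))
            families.append((d, s))
    return SelectionResult(
        summaries=pd.DataFrame(rows), population=pop, final_family_broods=final_broods
    )


def _line_shift(target_bsr: float, gen: GeneticConfig) -> float:
    """Founder breeding-value mean giving a line the target mean BSR."""
    tot = np.sqrt(gen.sigma2_a + gen.sigma2_m + 1.0)
    return float(norm.ppf(target_bsr) * tot) - gen.mu


def simulate_diallel_dataset(
    gen: GeneticConfig = GeneticConfig(),
    design: CrossDesign = CrossDesign(),
    seed: Optional[int] = None,
    n_f1_per_cell: int = 9,
    n_backcrosses: int = 223,
    brood_sizes: BroodSizeDistribution = BroodSizeDistribution(),
    male_line_bsr: float = 0.64,
    female_line_bsr: float = 0.35,
    n_bc_parent_families_per_line: int = 8,
) -> SimulatedDataset:
    """Full study-style dataset: parental broods, diallel F1s, backcrosses.

    Founder families of the two selection lines are seeded with
    breeding-value means that reproduce the lines' mean brood sex ratios
    (defaults 0.64 male-biased, 0.35 female-biased).  ``n_f1_per_cell``
    crosses are realized per cross-type x block cell of the enumerated
    diallel (the study realized 8-10 of the possible 12-16), and
    ``n_backcrosses`` of the enumerated reciprocal backcrosses of
    between-line F1 families to fresh selection-line families.
    """
    rng = np.random.default_rng(seed)
    pop = SimPopulation(gen)
    shift = {"M": _line_shift(male_line_bsr, gen), "F": _line_shift(female_line_bsr, gen)}

    # --- parental-generation families (Pf1-8 / Pm1-8, 4 + 4 per block)
    k = design.families_per_line_per_block
    fam_parents: dict[str, tuple[str, str]] = {}
    for b in range(1, design.n_blocks + 1):
        for line in ("F", "M"):
            for i in range(1, k + 1):
                fam = f"B{b}-{line}{i}"
                d = pop.add_founder(f"{fam}-pd", "female", rng, shift[line], line, b)
                s = pop.add_founder(f"{fam}-ps", "male", rng, shift[line], line, b)
                fam_parents[fam] = (d, s)

    plans: list[CrossPlan] = []
    fam_broods: dict[str, list[str]] = {}
    sizes = brood_sizes.sample(rng, len(fam_parents))
    for k2, (fam, (d, s)) in enumerate(fam_parents.items()):
        b = pop.block[pop.index[d]]
        line = pop.source[pop.index[d]]
        ids = pop.spawn_brood(d, s, int(sizes[k2]), rng, prefix=f"{fam}-P", block=b, generation=1)
        fam_broods[fam] = ids
        plans.append(CrossPlan(f"{fam}-P", d, s, b, f"parental-{line}", 1))

    records: list[BroodRecord] = [
        _brood_record(pop, p, fam_broods[p.cross_id.rsplit("-P", 1)[0]]) for p in plans
    ]

    # --- F1 diallel
    used: set[str] = set()
    cells: dict[tuple[int, str], list[F1Cross]] = {}
    for cr in enumerate_f1_design(design):
        cells.setdefault((cr.block, cr.cross_type), []).append(cr)
    f1_crosses: list[tuple[CrossPlan, list[str]]] = []
    for (b, ctype), cell in sorted(cells.items()):
        take = rng.choice(len(cell), size=min(n_f1_per_cell, len(cell)), replace=False)
        for j in sorted(take):
            cr = cell[j]
            dam = pick_from(pop, rng, fam_broods[cr.dam_family], "female", used)
            sire = pick_from(pop, rng, fam_broods[cr.sire_family], "male", used)
            if dam is None or sire is None:
                continue
            cid = f"F1-{cr.block}-{ctype}-{cr.dam_family}x{cr.sire_family}"
            plan = CrossPlan(cid, dam, sire, cr.block, ctype, 2)
            size = int(brood_sizes.sample(rng, 1)[0])
            ids = pop.spawn_brood(dam, sire, size, rng, prefix=cid, block=cr.block, generation=2)
            records.append(_brood_record(pop, plan, ids))
            f1_crosses.append((plan, ids))

    # --- fresh selection-line families for backcross parents (Pf9-16 / Pm9-16)
    bc_parent_broods: list[tuple[str, list[str]]] = []
    for line in ("F", "M"):
        for i in range(1, n_bc_parent_families_per_line + 1):
            fam = f"BCP-{line}{i}"
            b = 1 + (i - 1) % design.n_blocks
            d = pop.add_founder(f"{fam}-pd", "female", rng, shift[line], line, b)
            s = pop.add_founder(f"{fam}-ps", "male", rng, shift[line], line, b)
            size = int(brood_sizes.sample(rng, 1)[0])
            ids = pop.spawn_brood(d, s, size, rng, prefix=f"{fam}-P", block=b, generation=1)
            plan = CrossPlan(f"{fam}-P", d, s, b, f"parental-{line}", 1)
            records.append(_brood_record(pop, plan, ids))
            bc_parent_broods.append((line, ids))

    # --- backcrosses: between-line F1 families x selection-line families
    hybrid_f1 = [(p, ids) for p, ids in f1_crosses if p.cross_type in ("FM", "MF")]
    n_pf = len(bc_parent_broods)
    _, bc_pairs = enumerate_backcross_design(len(hybrid_f1), n_pf, reciprocal=True)
    if bc_pairs:
        take = rng.choice(len(bc_pairs), size=min(n_backcrosses, len(bc_pairs)), replace=False)
        for j in sorted(take):
            fi, pi, direction = bc_pairs[j]
            f1_plan, f1_ids = hybrid_f1[fi]
            pline, p_ids = bc_parent_broods[pi]
            if direction == "f1_dam":
                dam = pick_from(pop, rng, f1_ids, "female", used)
                sire = pick_from(pop, rng, p_ids, "male", used)
            else:
                dam = pick_from(pop, rng, p_ids, "female", used)
                sire = pick_from(pop, rng, f1_ids, "male", used)
            if dam is None or sire is None:
                continue
            cid = f"BC-{j}"
            plan = CrossPlan(cid, dam, sire, f1_plan.block, f"BC-{pline}", 3)
            size = int(brood_sizes.sample(rng, 1)[0])
            ids = pop.spawn_brood(dam, sire, size, rng, prefix=cid, block=plan.block, generation=3)
            records.append(_brood_record(pop, plan, ids))

    return SimulatedDataset(
        pedigree=pop.pedigree(),
        broods=records,
        phenotypes=pop.phenotype_frame(),
        true_params=gen,
        seed=seed,
        population=pop,
    )


def pick_from(
    pop: SimPopulation,
    rng: np.random.Generator,
    ids: Sequence[str],
    sex: str,
    used: set,
) -> Optional[str]:
    members = pop.members_of_sex(ids, sex)
    if not members:
        return None
    fresh = [m for m in members if m not in used]
    choice = str(rng.choice(fresh if fresh else members))
    used.add(choice)
    return choice


def _brood_record(pop: SimPopulation, plan: CrossPlan, ids: Sequence[str]) -> BroodRecord:
    n_male = sum(pop.sex[pop.index[i]] == "male" for i in ids)
    return BroodRecord(
        cross_id=plan.cross_id,
        dam=plan.dam,
        sire=plan.sire,
        block=plan.block,
        cross_type=plan.cross_type,
        generation=plan.generation,
        n_male=n_male,
        n_female=len(ids) - n_male,
        brood_index=1,
    )


def random_pedigree(
    n: int,
    rng: Optional[np.random.Generator] = None,
    founder_fraction: float = 0.15,
    missing_parent_prob: float = 0.1,
) -> PedigreeTable:
    """Random valid pedigree for property tests.

    Founders first; each later individual draws a sire among earlier males
    and a dam among earlier females, with occasional single unknown parents.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_founders = max(2, int(n * founder_fraction))
    sexes = ["male", "female"]
    recs: list[PedigreeRecord] = []
    males, females = [], []
    for i in range(n):
        sex = sexes[int(rng.integers(2))] if i >= 2 else sexes[i % 2]
        sid = did = None
        if i >= n_founders:
            if males and rng.uniform() > missing_parent_prob:
                sid = males[int(rng.integers(len(males)))]
            if females and rng.uniform() > missing_parent_prob:
                did = females[int(rng.integers(len(females)))]
        rid = f"ind{i}"
        recs.append(PedigreeRecord(rid, sid, did, sex, generation=0))
        (males if sex == "male" else females).append(rid)
    return validate_and_sort(recs)
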
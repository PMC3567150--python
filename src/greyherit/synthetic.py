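"""Synthetic Lipizzan-style study generator.

Produces pedigrees, two-locus genotypes (gene dropping), polygenic breeding
values (Mendelian-sampling recursion) and longitudinal phenotype records
with exactly the statistical structure the animal model assumes:

    y = stud.sex.year class + beta_age * age_years
        + alpha_STX17 * I(Gg) + a_ASIP * add_code + d_ASIP * dom_code
        + u (polygenic, Var = A * V_POLY)
        + pe (per animal, Var = V_pe) + e (per record, Var = V_e)

Only grey animals (GG/Gg) are phenotyped, as in the study population.  The
four shipped trait configurations (melanoma grade 0-5, grey level L* 0-100,
vitiligo grade 0-3, speckling grade 0-3) carry the study's fixed-effect and
variance-component parameterisation; greying is a young-horse trait
(records at <= 84 months), the other three are adult traits (>= 84 months).

Phenotypes are continuous by default; ``round_to_scale`` optionally snaps
graded traits onto their ordinal scales as a robustness stressor.
All operations are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, inbreeding
from .genotypes import GenotypeTable

__all__ = [
    "TraitConfig",
    "StudyDesign",
    "table1_configs",
    "default_design",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_study",
]

#: age-window bounds in months, inclusive; 84 months (7 years) belongs to both
AGE_WINDOWS = {"young": (12, 84), "old": (84, 216)}


def _rng(seed, domain):
    """Deterministic generator, domain-separated so that the four simulation
    stages never share a random stream even when given the same seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), domain]))


@dataclass
class TraitConfig:
    """Parameters of one trait's generating model (trait units as listed).

    Variances are in squared trait units; ``alpha_stx17`` is the Gg-vs-GG
    substitution effect; ``asip_a``/``asip_d`` the ASIP additive and
    dominance values; ``beta_age`` is per year of age.  ``class_variance``
    is the variance of stud.sex.year class effects (None: 10% of V_P).
    """

    name: str
    v_poly: float
    v_pe: float
    v_e: float
    alpha_stx17: float
    asip_a: float = 0.0
    asip_d: float = 0.0
    beta_age: float = 0.0
    age_window: str = "old"
    scale: tuple = (0.0, 5.0)
    scale_step: float | None = None
    p_g: float = 0.85
    p_a: float = 0.51
    class_variance: float | None = None

    def __post_init__(self):
        if min(self.v_poly, self.v_pe, self.v_e) < 0:
            raise ValueError("variances must be non-negative")
        for p in (self.p_g, self.p_a):
            if not 0.0 <= p <= 1.0:
                raise ValueError("allele frequencies must lie in [0, 1]")
        if self.age_window not in AGE_WINDOWS:
            raise ValueError(f"age_window must be one of {sorted(AGE_WINDOWS)}")

    @property
    def v_stx17(self):
        return 2.0 * self.p_g * (1 - self.p_g) * self.alpha_stx17**2

    @property
    def v_asip(self):
        alpha = self.asip_a + (self.p_a - (1 - self.p_a)) * self.asip_d
        return 2.0 * self.p_a * (1 - self.p_a) * alpha**2

    @property
    def v_phenotypic(self):
        return self.v_poly + self.v_stx17 + self.v_asip + self.v_pe + self.v_e

    def resolved_class_variance(self):
        if self.class_variance is not None:
            return self.class_variance
        return 0.1 * self.v_phenotypic


@dataclass
class StudyDesign:
    """Population and measurement design of a simulated study.

    The defaults emulate the source study's scale: a multi-generation
    closed stud population of ~1,100 animals descending from reused sires
    (mean ~6 offspring) and dams (mean ~2.3), measured repeatedly across
    6 studs over the years 1999-2007.
    """

    n_founders: int = 150
    n_generations: int = 5
    offspring_per_generation: int = 240
    mean_offspring_per_sire: float = 5.97
    mean_offspring_per_dam: float = 2.26
    n_studs: int = 6
    years: tuple = tuple(range(1999, 2008))
    mean_records_per_animal: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.n_generations, self.n_studs) <= 0:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def _config_path():
    return resources.files("greyherit") / "configs" / "lipizzan.yaml"


def table1_configs(path=None) -> dict:
    """The four shipped trait configurations (study parameterisation)."""
    if path is None:
        raw = yaml.safe_load(_config_path().read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    configs = {}
    for name, kw in raw["traits"].items():
        kw = dict(kw)
        if "scale" in kw:
            kw["scale"] = tuple(kw["scale"])
        configs[name] = TraitConfig(name=name, **kw)
    return configs


def default_design(path=None, **overrides) -> StudyDesign:
    if path is None:
        raw = yaml.safe_load(_config_path().read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    kw = dict(raw.get("design", {}))
    kw.update(overrides)
    if "years" in kw:
        kw["years"] = tuple(kw["years"])
    return StudyDesign(**kw)


def simulate_pedigree(design: StudyDesign) -> Pedigree:
    """Multi-generation pedigree with sire/dam reuse.

    Generation 0 are founders; each later generation's parents are drawn
    from the previous generation, with the number of active sires/dams set
    by the target mean family sizes.
    """
    rng = _rng(design.seed, 1)
    records = []
    prev_m, prev_f = [], []
    counter = 0
    base_year = 1980

    def new_id():
        nonlocal counter
        counter += 1
        return f"H{counter:05d}"

    for g in range(design.n_generations):
        n_off = design.n_founders if g == 0 else design.offspring_per_generation
        cur_m, cur_f = [], []
        if g > 0 and (not prev_m or not prev_f):
            raise ValueError(
                "infeasible design: no candidate sires or dams in "
                f"generation {g - 1}"
            )
        if g > 0:
            n_sires = max(1, round(n_off / design.mean_offspring_per_sire))
            n_dams = max(1, round(n_off / design.mean_offspring_per_dam))
            sires = rng.choice(prev_m, size=min(n_sires, len(prev_m)), replace=False)
            dams = rng.choice(prev_f, size=min(n_dams, len(prev_f)), replace=False)
        for _ in range(n_off):
            a = new_id()
            sex = "M" if rng.random() < 0.5 else "F"
            (cur_m if sex == "M" else cur_f).append(a)
            if g == 0:
                records.append(
                    dict(id=a, sire=None, dam=None, sex=sex, birth_year=base_year)
                )
            else:
                records.append(
                    dict(
                        id=a,
                        sire=rng.choice(sires),
                        dam=rng.choice(dams),
                        sex=sex,
                        birth_year=base_year + 4 * g,
                    )
                )
        prev_m, prev_f = cur_m, cur_f
    return Pedigree.from_records(records)


def drop_genotypes(ped: Pedigree, p_g=0.85, p_a=0.51, seed=0):
    """Mendelian gene dropping at the two unlinked loci.

    Founders draw genotypes from Hardy-Weinberg proportions at the given
    allele frequencies; offspring inherit one uniformly chosen allele per
    known parent (alleles of an unknown parent come from the founder pool).
    Returns (GenotypeTable, colour Series); colour is grey iff >= 1 G.
    """
    rng = _rng(seed, 2)
    alleles = {}
    for locus, p in (("stx17", p_g), ("asip", p_a)):
        al = np.empty((ped.n, 2), dtype=np.int8)
        for i in range(ped.n):
            for k, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent < 0:
                    al[i, k] = rng.random() < p
                else:
                    al[i, k] = al[parent, rng.integers(2)]
        alleles[locus] = al

    def labels(locus, ref, alt):
        c = alleles[locus].sum(axis=1)
        return np.select([c == 2, c == 1], [ref * 2, ref + alt], default=alt * 2)

    gt = GenotypeTable(
        pd.DataFrame(
            {
                "id": ped.ids,
                "stx17": labels("stx17", "G", "g"),
                "asip": labels("asip", "A", "a"),
                "stx17_source": "measured",
                "asip_source": "measured",
            }
        )
    )
    grey = alleles["stx17"].sum(axis=1) > 0
    colour = pd.Series(
        np.where(grey, "grey", "coloured"), index=pd.Index(ped.ids, name="id")
    )
    return gt, colour


def simulate_breeding_values(ped: Pedigree, G0, seed=0) -> np.ndarray:
    """Polygenic breeding values by the Mendelian-sampling recursion.

    G0 is the (k x k) polygenic covariance matrix among traits (a scalar is
    accepted for one trait).  Founders draw u ~ N(0, G0); an offspring gets
    the parent average plus a Mendelian-sampling deviation with covariance
    G0 * d_i, d_i = 0.5 - 0.25 (F_sire + F_dam).  The implied joint
    covariance of the stacked vector is A (x) G0.
    """
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    if not np.allclose(G0, G0.T):
        raise ValueError("G0 must be symmetric")
    w, V = np.linalg.eigh(G0)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError("G0 must be positive semi-definite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))  # G0 = L L'
    k = G0.shape[0]
    rng = _rng(seed, 3)
    F = inbreeding(ped)
    u = np.zeros((ped.n, k))
    z = rng.standard_normal((ped.n, k))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            mean = 0.5 * (u[s] + u[d])
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mean = 0.5 * u[p]
            dvar = 0.75 - 0.25 * F[p]
        else:
            mean = 0.0
            dvar = 1.0
        u[i] = mean + np.sqrt(dvar) * (L @ z[i])
    return u


def simulate_phenotypes(
    ped: Pedigree,
    genotypes: GenotypeTable,
    breeding_values,
    cfg: TraitConfig,
    design: StudyDesign,
    seed=0,
    round_to_scale: bool = False,
) -> pd.DataFrame:
    """Longitudinal records for one trait on the grey animals.

    Returns a DataFrame with columns animal, trait, value, age_months,
    stud, sex, year plus the simulated truth columns class_effect, u, pe
    (kept for exact-recovery tests; the model never sees them).
    """
    rng = _rng(seed, 4)
    u = np.asarray(breeding_values, dtype=float).reshape(ped.n, -1)[:, 0]
    lo, hi = AGE_WINDOWS[cfg.age_window]
    class_sd = np.sqrt(cfg.resolved_class_variance())
    class_effects = {}
    studs = [f"S{j + 1}" for j in range(design.n_studs)]

    stx = genotypes.codes(ped.ids, "stx17")
    asip = genotypes.codes(ped.ids, "asip")
    pe_all = rng.standard_normal(ped.n) * np.sqrt(cfg.v_pe)
    stud_of = rng.choice(studs, size=ped.n)

    rows = []
    for i, animal in enumerate(ped.ids):
        if not stx[i] >= 1:  # only grey animals (Gg=1, GG=2) are phenotyped
            continue
        n_rec = max(1, rng.poisson(design.mean_records_per_animal))
        ages = np.sort(rng.integers(lo, hi + 1, size=n_rec))
        years = rng.choice(design.years, size=n_rec)
        sex = ped.sex[i] if ped.sex[i] in ("M", "F") else "U"
        for age, year in zip(ages, years):
            key = (stud_of[i], sex, int(year))
            if key not in class_effects:
                class_effects[key] = rng.standard_normal() * class_sd
            gg_code = 1.0 if stx[i] == 1 else 0.0  # Gg = 1, GG = 0
            if np.isfinite(asip[i]):
                # additive code counts a alleles (AA=0, Aa=1, aa=2)
                add_code = 2.0 - asip[i]
                dom_code = 1.0 if asip[i] == 1 else 0.0
            else:
                add_code = dom_code = 0.0
            value = (
                class_effects[key]
                + cfg.beta_age * age / 12.0
                + cfg.alpha_stx17 * gg_code
                + cfg.asip_a * add_code
                + cfg.asip_d * dom_code
                + u[i]
                + pe_all[i]
                + rng.standard_normal() * np.sqrt(cfg.v_e)
            )
            rows.append(
                (
                    animal,
                    cfg.name,
                    value,
                    int(age),
                    stud_of[i],
                    sex,
                    int(year),
                    class_effects[key],
                    u[i],
                    pe_all[i],
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "animal",
            "trait",
            "value",
            "age_months",
            "stud",
            "sex",
            "year",
            "class_effect",
            "u",
            "pe",
        ],
    )
    if round_to_scale and cfg.scale_step:
        lo_s, hi_s = cfg.scale
        df["value"] = np.clip(
            np.round(df["value"] / cfg.scale_step) * cfg.scale_step, lo_s, hi_s
        )
    return df


def simulate_study(cfg: TraitConfig, design: StudyDesign, seed=None):
    """Convenience wrapper: pedigree + genotypes + breeding values + records.

    Returns (ped, genotype_table, colour, records).  The four stages use
    domain-separated streams derived from the one master seed.  The
    pedigree and gene-dropping stages depend only on the master seed, so
    separate per-trait runs at one seed share the population; the
    breeding-value and record stages are additionally salted with the
    trait name, so different traits never share polygenic or residual
    draws (simulate the traits jointly via a G0 matrix when a polygenic
    correlation is wanted).
    """
    import zlib

    seed = design.seed if seed is None else seed
    trait_seed = int(
        np.random.SeedSequence(
            [int(seed), zlib.crc32(cfg.name.encode())]
        ).generate_state(1)[0]
        % (2**31 - 1)
    )
    ped = simulate_pedigree(replace(design, seed=seed))
    gt, colour = drop_genotypes(ped, p_g=cfg.p_g, p_a=cfg.p_a, seed=seed)
    u = simulate_breeding_values(ped, cfg.v_poly, seed=trait_seed)
    records = simulate_phenotypes(ped, gt, u, cfg, design, seed=trait_seed)
    return ped, gt, colour, records
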
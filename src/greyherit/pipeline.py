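"""End-to-end orchestration: data preparation, univariate analyses, the
three genetic-correlation scenarios, and report tables.

Trait records are age-filtered before analysis: grey level is a
young-horse trait (measurements at 84 months = 7 years old and younger),
melanoma, vitiligo and speckling are adult traits (84 months and older);
the 7-year boundary belongs to both windows.  Genetic correlations between
trait pairs are estimated under three scenarios:

1. polygenic model, all genotyped horses (major genes ignored);
2. polygenic model plus STX17 (and, for melanoma, ASIP) fixed covariates;
3. polygenic model on the homozygous (GG) subset only.

A shared major gene inflates scenario-1 polygenic correlations; the drop
from scenario 1 to scenarios 2/3 measures the pleiotropy attributable to
the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .animal_model import (
    BivariateFit,
    FitResult,
    ModelSpec,
    build_design,
    reml_bivariate,
    reml_univariate,
    standardize_ebv,
)
from .decomposition import (
    CorrelationResult,
    DecompositionResult,
    LocusEffect,
    compose_phenotypic_correlation,
    decompose,
    round_half_up,
)
from .genotypes import GenotypeTable, allele_frequencies
from .pedigree import Pedigree, build_A_inverse
from .synthetic import AGE_WINDOWS, TraitConfig

__all__ = [
    "ScenarioSpec",
    "PreparedDataset",
    "prepare",
    "model_spec_for",
    "gg_subset",
    "run_univariate_analysis",
    "run_scenarios",
    "report",
    "ebv_export",
]


@dataclass
class ScenarioSpec:
    """One of the three correlation scenarios."""

    scenario: int
    include_major_genes: bool = False
    gg_only: bool = False

    @classmethod
    def of(cls, scenario: int):
        if scenario == 1:
            return cls(1)
        if scenario == 2:
            return cls(2, include_major_genes=True)
        if scenario == 3:
            return cls(3, gg_only=True)
        raise ValueError("scenario must be 1, 2 or 3")


@dataclass
class PreparedDataset:
    """Filtered records for one trait plus an exact accounting of drops."""

    records: pd.DataFrame
    trait: str
    filter_log: dict = field(default_factory=dict)


def prepare(
    records: pd.DataFrame,
    cfg: TraitConfig,
    enforce_scale: bool = True,
    check_steps: bool = False,
) -> PreparedDataset:
    """Apply the trait's age window and (optionally) scale checks.

    ``enforce_scale`` rejects values outside the trait's measurement scale;
    ``check_steps`` additionally requires graded traits to sit on their
    grading increments (e.g. half-grades for melanoma).  Scale checks are
    meant for observational data QC; the simulator emits continuous values.
    """
    df = records[records["trait"] == cfg.name] if "trait" in records else records
    n_input = len(df)
    lo, hi = AGE_WINDOWS[cfg.age_window]
    in_window = (df["age_months"] >= lo) & (df["age_months"] <= hi)
    n_age = int((~in_window).sum())
    df = df[in_window]
    n_scale = 0
    if enforce_scale:
        smin, smax = cfg.scale
        ok = (df["value"] >= smin) & (df["value"] <= smax)
        if check_steps and cfg.scale_step:
            frac = np.abs(
                df["value"] / cfg.scale_step
                - np.round(df["value"] / cfg.scale_step)
            )
            ok &= frac < 1e-9
        n_scale = int((~ok).sum())
        df = df[ok]
    if df.empty:
        raise ValueError(
            f"no {cfg.name} records remain after age/scale filtering"
        )
    log = {
        "n_input": n_input,
        "n_age_dropped": n_age,
        "n_scale_dropped": n_scale,
        "n_output": len(df),
    }
    return PreparedDataset(df.reset_index(drop=True), cfg.name, log)


def model_spec_for(cfg: TraitConfig, scenario: ScenarioSpec) -> ModelSpec:
    """Fixed-effect layout for one trait under a scenario.

    ASIP enters only for traits with a non-zero configured ASIP effect
    (melanoma in the study parameterisation)."""
    use_genes = scenario.include_major_genes
    return ModelSpec(
        trait=cfg.name,
        stx17_covariate=use_genes,
        asip_additive=use_genes and cfg.asip_a != 0.0,
    )


def gg_subset(gt: GenotypeTable, strict: bool = False):
    """Animal ids with GG status (measured, or deduced unless ``strict``)."""
    frame = gt.frame
    is_gg = frame["stx17"] == "GG"
    if strict:
        is_gg &= frame["stx17_source"] == "measured"
    ids = set(frame.loc[is_gg, "id"])
    if not ids:
        raise ValueError("no homozygous (GG) animals available for scenario 3")
    return ids


def _genotyped_records(records, gt, need_asip=False):
    known = set(gt.frame.loc[gt.known_mask("stx17"), "id"])
    if need_asip:
        known &= set(gt.frame.loc[gt.known_mask("asip"), "id"])
    return records[records["animal"].astype(str).isin(known)]


def run_univariate_analysis(
    ped: Pedigree,
    gt: GenotypeTable,
    prepared: PreparedDataset,
    cfg: TraitConfig,
    scenario: int = 2,
    A_inv=None,
    strict_gg: bool = False,
    **fit_kwargs,
):
    """Fit one trait and decompose its variance.

    Returns (FitResult, DecompositionResult).  Under scenario 2 the fitted
    STX17/ASIP regression coefficients are the substitution effects whose
    2pq alpha^2 variances enter the partition; scenarios 1 and 3 have no
    locus terms (h2 = h2_POLY).
    """
    sc = ScenarioSpec.of(scenario)
    records = _genotyped_records(prepared.records, gt, need_asip=False)
    if sc.gg_only:
        ids = gg_subset(gt, strict=strict_gg)
        records = records[records["animal"].astype(str).isin(ids)]
    if records.empty:
        raise ValueError(f"scenario {scenario}: no analysable records")
    spec = model_spec_for(cfg, sc)
    design = build_design(records, spec, gt=gt, ped=ped)
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    fit = reml_univariate(design, A_inv, **fit_kwargs)

    effects = []
    if sc.include_major_genes:
        animals = records["animal"].astype(str).unique()
        fe = fit.fixed_effects.set_index("term")["estimate"]
        p_g = allele_frequencies(gt, animals, "stx17").p
        effects.append(
            LocusEffect("stx17", a=float(fe["alpha_stx17"]), p=p_g,
                        kind="two_genotype")
        )
        if "alpha_asip" in fe.index:
            p_a = allele_frequencies(gt, animals, "asip").p
            effects.append(LocusEffect("asip", a=float(fe["alpha_asip"]), p=p_a))
    dec = decompose(fit.components, effects)
    return fit, dec


def run_scenarios(
    cfg1: TraitConfig,
    cfg2: TraitConfig,
    prepared1: PreparedDataset,
    prepared2: PreparedDataset,
    ped: Pedigree,
    gt: GenotypeTable,
    A_inv=None,
    scenarios=(1, 2, 3),
    strict_gg: bool = False,
    paired: bool = False,
    **fit_kwargs,
):
    """Bivariate polygenic-correlation analysis under the three scenarios.

    Returns (list of CorrelationResult, dict scenario -> BivariateFit).
    """
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    results, fits = [], {}
    for s in scenarios:
        sc = ScenarioSpec.of(s)
        try:
            r1 = _genotyped_records(prepared1.records, gt)
            r2 = _genotyped_records(prepared2.records, gt)
            if sc.gg_only:
                ids = gg_subset(gt, strict=strict_gg)
                r1 = r1[r1["animal"].astype(str).isin(ids)]
                r2 = r2[r2["animal"].astype(str).isin(ids)]
            if r1.empty or r2.empty:
                raise ValueError("no analysable records")
            d1 = build_design(r1, model_spec_for(cfg1, sc), gt=gt, ped=ped)
            d2 = build_design(r2, model_spec_for(cfg2, sc), gt=gt, ped=ped)
            fit = reml_bivariate(d1, d2, A_inv, paired=paired, **fit_kwargs)
        except Exception as exc:
            raise RuntimeError(
                f"scenario {s} ({cfg1.name}, {cfg2.name}) failed: {exc}"
            ) from exc
        h2 = [
            fit.G0[t, t] / (fit.G0[t, t] + fit.PE0[t, t] + fit.R0[t, t])
            for t in range(2)
        ]
        r_p = compose_phenotypic_correlation(
            np.clip(fit.r_poly, -1.0, 1.0), np.clip(fit.r_e, -1.0, 1.0),
            h2[0], h2[1]
        )
        results.append(
            CorrelationResult(
                trait_pair=(cfg1.name, cfg2.name),
                scenario=s,
                r_poly=float(np.clip(fit.r_poly, -1.0, 1.0)),
                r_poly_se=fit.r_poly_se,
                r_e=float(np.clip(fit.r_e, -1.0, 1.0)),
                r_e_se=fit.r_e_se,
                r_p=float(r_p),
            )
        )
        fits[s] = fit
    return results, fits


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_TABLE2_ROWS = [
    ("v_p", "phenotypic_variance"),
    ("repeatability", "repeatability"),
    ("c2", "explained_permanent_environment"),
    ("h2", "narrow_sense_heritability"),
    ("h2_poly", "polygenic_heritability"),
    ("h2_stx17", "stx17_heritability"),
    ("h2_asip", "asip_heritability"),
]


def report(
    fits: dict | None = None,
    decompositions: dict | None = None,
    correlations=(),
) -> dict:
    """Assemble the three report tables as DataFrames.

    ``fits``/``decompositions`` map trait name -> FitResult /
    DecompositionResult; ``correlations`` is a flat list of
    CorrelationResult.  Empty inputs yield empty tables with headers.
    """
    fits = fits or {}
    decompositions = decompositions or {}

    rows = []
    for trait, fit in fits.items():
        fe = fit.fixed_effects.set_index("term")
        for term in ("age_years", "alpha_stx17", "alpha_asip"):
            if term in fe.index:
                rows.append(
                    dict(
                        trait=trait,
                        parameter=term,
                        estimate=float(fe.loc[term, "estimate"]),
                        se=float(fe.loc[term, "se"]),
                    )
                )
        for comp in ("v_poly", "v_pe", "v_e"):
            rows.append(
                dict(
                    trait=trait,
                    parameter=comp,
                    estimate=fit.components.get(comp, 0.0),
                    se=fit.se.get(comp, np.nan),
                )
            )
    effects_table = pd.DataFrame(
        rows, columns=["trait", "parameter", "estimate", "se"]
    )

    part_cols = {}
    for trait, dec in decompositions.items():
        part_cols[trait] = [
            round_half_up(getattr(dec, attr)) for attr, _ in _TABLE2_ROWS
        ]
    partition_table = pd.DataFrame(
        part_cols, index=[label for _, label in _TABLE2_ROWS]
    )
    partition_table.index.name = "genetic_parameter"

    corr_rows = [
        dict(
            trait_1=c.trait_pair[0],
            trait_2=c.trait_pair[1],
            scenario=c.scenario,
            r_poly=c.r_poly,
            r_poly_se=c.r_poly_se,
            r_e=c.r_e,
            r_e_se=c.r_e_se,
            r_p=c.r_p,
        )
        for c in correlations
    ]
    correlation_table = pd.DataFrame(
        corr_rows,
        columns=[
            "trait_1",
            "trait_2",
            "scenario",
            "r_poly",
            "r_poly_se",
            "r_e",
            "r_e_se",
            "r_p",
        ],
    )
    return {
        "effects": effects_table,
        "partition": partition_table,
        "correlations": correlation_table,
    }


def ebv_export(fit: BivariateFit, gt: GenotypeTable) -> pd.DataFrame:
    """Plot-ready standardized EBVs with STX17 genotype labels.

    Standardization (mean 0, SD 1) is over animals with records, the set
    shown in the breeding-value scatter plots.
    """
    ebv = fit.ebv
    mask = ebv["has_records"].values
    out = pd.DataFrame({"id": ebv["id"]})
    for col in ebv.columns:
        if col.startswith("ebv_"):
            out[f"std_{col}"] = standardize_ebv(ebv[col].values, mask)
    out["stx17"] = [gt.get(a, "stx17") for a in ebv["id"]]
    out["has_records"] = mask
    return out[mask].reset_index(drop=True)


def write_report(tables: dict, out_dir):
    """Write the report bundle as CSV files; returns the paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=name == "partition")
        paths[name] = p
    return paths
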
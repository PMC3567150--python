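"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pandas as pd
import pytest

from greyherit import (
    ModelSpec,
    Pedigree,
    StudyDesign,
    TraitConfig,
    build_A,
    build_design,
    drop_genotypes,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)


@pytest.fixture
def trio_pedigree():
    """Sire, dam, one offspring."""
    return Pedigree.from_records(
        [
            dict(id="S", sire=None, dam=None, sex="M"),
            dict(id="D", sire=None, dam=None, sex="F"),
            dict(id="K", sire="S", dam="D", sex="M"),
        ]
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and their (inbred) offspring."""
    return Pedigree.from_records(
        [
            dict(id="A", sire=None, dam=None),
            dict(id="B", sire=None, dam=None),
            dict(id="C", sire="A", dam="B"),
            dict(id="D", sire="A", dam="B"),
            dict(id="E", sire="C", dam="D"),
        ]
    )


def random_pedigree(n, seed, p_founder=0.25):
    """Random valid pedigree of n animals (for property-style checks)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            records.append(dict(id=f"R{i}", sire=None, dam=None))
        else:
            s, d = rng.integers(0, i, size=2)
            records.append(dict(id=f"R{i}", sire=f"R{s}", dam=f"R{d}"))
    return Pedigree.from_records(records)


def tiny_study(seed, n_founders=4, n_offspring=6, mean_records=1.5, v=(2.0, 1.0, 1.5)):
    """A <=10-animal study with repeated records, for dense-oracle checks."""
    ped = None
    for offset in range(20):  # skip founder draws that are single-sex
        design = StudyDesign(
            n_founders=n_founders,
            n_generations=2,
            offspring_per_generation=n_offspring,
            mean_records_per_animal=mean_records,
            n_studs=1,
            years=(2000, 2001),
            seed=seed + 1000 * offset,
        )
        try:
            ped = simulate_pedigree(design)
            break
        except ValueError:
            continue
    assert ped is not None
    seed = design.seed
    gt, _ = drop_genotypes(ped, p_g=0.9, seed=seed + 1)
    u = simulate_breeding_values(ped, v[0], seed=seed + 2)
    cfg = TraitConfig(
        name="toy", v_poly=v[0], v_pe=v[1], v_e=v[2], alpha_stx17=-0.8,
        age_window="old",
    )
    records = simulate_phenotypes(ped, gt, u, cfg, design, seed=seed + 3)
    records = records.groupby("animal").head(2).reset_index(drop=True)
    design_obj = build_design(records, ModelSpec(trait="toy"), gt=gt, ped=ped)
    return ped, design_obj


def dense_reml_loglik(design, A, theta):
    """Brute-force REML criterion through the full covariance matrix V.

    Independent of the MME path: builds V = v_a ZAZ' + v_pe WW' + v_e I
    explicitly and evaluates
    -0.5 [log|V| + log|X'V^-1 X| + y'Py + (n - p) log 2pi].
    """
    v_a, v_pe, v_e = theta
    n = design.n
    q_a = design.ped.n
    Z = np.zeros((n, q_a))
    Z[np.arange(n), design.rec_animal] = 1.0
    rec = design.recorded_positions()
    pidx = {p: k for k, p in enumerate(rec)}
    W = np.zeros((n, len(rec)))
    W[np.arange(n), [pidx[p] for p in design.rec_animal]] = 1.0
    V = v_a * Z @ A @ Z.T + v_pe * W @ W.T + v_e * np.eye(n)
    Vi = np.linalg.inv(V)
    X = design.X
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XVX)
    return -0.5 * (
        ld_v + ld_x + design.y @ P @ design.y + (n - X.shape[1]) * np.log(2 * np.pi)
    )


def dense_reml_loglik_bivariate(d1, d2, A, G0, PE0, R0, pe_positions):
    """Dense REML criterion for the stacked two-trait model."""
    n1, n2 = d1.n, d2.n
    n = n1 + n2
    q_a = d1.ped.n
    q_w = len(pe_positions)
    pidx = {p: k for k, p in enumerate(pe_positions)}
    Z = np.zeros((n, 2 * q_a))
    Z[np.arange(n1), d1.rec_animal] = 1.0
    Z[n1 + np.arange(n2), q_a + d2.rec_animal] = 1.0
    W = np.zeros((n, 2 * q_w))
    W[np.arange(n1), [pidx[p] for p in d1.rec_animal]] = 1.0
    W[n1 + np.arange(n2), [q_w + pidx[p] for p in d2.rec_animal]] = 1.0
    V = Z @ np.kron(G0, A) @ Z.T + W @ np.kron(PE0, np.eye(q_w)) @ W.T
    V += np.diag(np.concatenate([np.full(n1, R0[0, 0]), np.full(n2, R0[1, 1])]))
    X = np.zeros((n, d1.n_fixed + d2.n_fixed))
    X[:n1, : d1.n_fixed] = d1.X
    X[n1:, d1.n_fixed :] = d2.X
    y = np.concatenate([d1.y, d2.y])
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XVX)
    return -0.5 * (ld_v + ld_x + y @ P @ y + (n - X.shape[1]) * np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# exhaustive genotype-deduction oracle
# ---------------------------------------------------------------------------

_GAMETES = {2: (1,), 1: (0, 1), 0: (0,)}


def enumerate_consistent_genotypes(ped, colour=None, measured_counts=None):
    """All Mendelian-consistent single-locus assignments for a small pedigree.

    Returns a list of tuples of allele counts (2=homref, 1=het, 0=homalt) in
    pedigree order; ``colour`` maps ids to grey/coloured (dominant
    reference allele), ``measured_counts`` maps ids to fixed counts.
    """
    colour = colour or {}
    measured_counts = measured_counts or {}
    domains = []
    for a in ped.ids:
        dom = {0, 1, 2}
        if a in measured_counts:
            dom = {measured_counts[a]}
        c = colour.get(a)
        if c == "coloured":
            dom &= {0}
        elif c == "grey":
            dom -= {0}
        domains.append(sorted(dom))
    out = []
    for assign in itertools.product(*domains):
        ok = True
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            sa = _GAMETES[assign[s]] if s >= 0 else (0, 1)
            da = _GAMETES[assign[d]] if d >= 0 else (0, 1)
            if s < 0 and d < 0:
                continue
            if not any(x + y == assign[i] for x in sa for y in da):
                ok = False
                break
        if ok:
            out.append(assign)
    return out
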
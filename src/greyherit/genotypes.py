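"""Two-locus genotype tables, pedigree-based genotype deduction, and
allele-frequency counting.

Greying in horses is dominant: a grey horse carries at least one copy of
the STX17 duplication (genotype GG or Gg) and a non-grey (coloured) horse
is gg.  Coat colour therefore carries genotype information that can be
propagated through the pedigree: a grey parent with a coloured offspring
must be Gg, a grey offspring of a coloured parent must be Gg, and further
genotypes follow from generic Mendelian elimination.  The ASIP (agouti)
locus has no colour rule here and is deduced by Mendelian elimination from
measured relatives only.

Deduction works on per-animal candidate-genotype sets: colour and measured
genotypes initialise the sets, nuclear-family elimination (Lange-Goradia
style) shrinks them to a fixed point, and small connected components are
then resolved exactly by enumeration of all Mendelian-consistent
assignments.  An animal is "deduced" when its candidate set is a singleton
it was not measured at.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GenotypeTable",
    "AlleleFrequencies",
    "MendelianError",
    "deduce_genotypes",
    "allele_frequencies",
    "load_genotypes",
    "load_colours",
]

#: locus -> (reference allele, alternative allele)
LOCI = {"stx17": ("G", "g"), "asip": ("A", "a")}

#: genotype labels indexed by reference-allele count, per locus
_LABELS = {
    "stx17": {2: "GG", 1: "Gg", 0: "gg"},
    "asip": {2: "AA", 1: "Aa", 0: "aa"},
}
_COUNTS = {loc: {v: k for k, v in lab.items()} for loc, lab in _LABELS.items()}

UNKNOWN = "unknown"


class MendelianError(ValueError):
    """Genotypes/colours that no Mendelian assignment can satisfy."""


@dataclass
class AlleleFrequencies:
    """Counted allele frequencies at one locus.

    p is the frequency of the reference allele (G for STX17, A for ASIP),
    q = 1 - p, over ``n_counted`` animals with a known genotype.
    """

    locus: str
    p: float
    n_counted: int

    @property
    def q(self):
        return 1.0 - self.p


class GenotypeTable:
    """Per-animal STX17 and ASIP genotypes with per-locus provenance.

    Backed by a DataFrame with columns id, stx17, asip, stx17_source,
    asip_source; genotype values are GG/Gg/gg, AA/Aa/aa or "unknown",
    sources are measured/deduced/unknown.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame["id"] = frame["id"].astype(str)
        for locus in LOCI:
            if locus not in frame.columns:
                frame[locus] = UNKNOWN
            src = f"{locus}_source"
            if src not in frame.columns:
                frame[src] = np.where(
                    frame[locus].isin(_COUNTS[locus]), "measured", UNKNOWN
                )
            bad = ~frame[locus].isin(list(_COUNTS[locus]) + [UNKNOWN])
            if bad.any():
                raise ValueError(
                    f"invalid {locus} genotype value(s): "
                    f"{sorted(frame.loc[bad, locus].unique())}"
                )
        if frame["id"].duplicated().any():
            raise ValueError("duplicate animal id in genotype table")
        self.frame = frame[
            ["id", "stx17", "asip", "stx17_source", "asip_source"]
        ].reset_index(drop=True)
        self._row = {a: i for i, a in enumerate(self.frame["id"])}

    @classmethod
    def empty(cls, animal_ids):
        return cls(pd.DataFrame({"id": [str(a) for a in animal_ids]}))

    def __len__(self):
        return len(self.frame)

    def get(self, animal_id, locus):
        i = self._row.get(str(animal_id))
        return UNKNOWN if i is None else self.frame.at[i, locus]

    def source(self, animal_id, locus):
        i = self._row.get(str(animal_id))
        return UNKNOWN if i is None else self.frame.at[i, f"{locus}_source"]

    def known_mask(self, locus):
        return self.frame[locus] != UNKNOWN

    def codes(self, animal_ids, locus):
        """Reference-allele counts (0/1/2) per animal, NaN when unknown."""
        cmap = _COUNTS[locus]
        return np.array(
            [float(cmap.get(self.get(a, locus), np.nan)) for a in animal_ids]
        )

    def restrict_to_measured(self):
        """Copy with all deduced entries reset to unknown."""
        frame = self.frame.copy()
        for locus in LOCI:
            src = f"{locus}_source"
            ded = frame[src] == "deduced"
            frame.loc[ded, locus] = UNKNOWN
            frame.loc[ded, src] = UNKNOWN
        return GenotypeTable(frame)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


def load_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for locus in LOCI:
        if locus in df.columns:
            df.loc[df[locus].isin(["", "NA", "."]), locus] = UNKNOWN
    return GenotypeTable(df)


def load_colours(path) -> pd.Series:
    """Colour CSV (id,colour with colour in {grey, coloured, unknown})."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colour = df["colour"].str.lower()
    ok = colour.isin(["grey", "coloured", "unknown", ""])
    if not ok.all():
        raise ValueError(
            f"invalid colour label(s): {sorted(colour[~ok].unique())}"
        )
    return pd.Series(colour.replace("", UNKNOWN).values, index=df["id"].astype(str))


# ---------------------------------------------------------------------------
# Genotype deduction
# ---------------------------------------------------------------------------

_GAMETES = {2: (1,), 1: (0, 1), 0: (0,)}  # alleles a genotype can transmit


def _child_ok(child, sire_g, dam_g):
    """Can `child` (allele count) arise from parent genotypes (None = free)?"""
    sa = _GAMETES[sire_g] if sire_g is not None else (0, 1)
    da = _GAMETES[dam_g] if dam_g is not None else (0, 1)
    return any(a + b == child for a in sa for b in da)


def _eliminate(ped: Pedigree, domains, locus):
    """Nuclear-family genotype elimination to a fixed point (in place).

    domains: list of sets of allele counts per pedigree position.
    Raises MendelianError when a domain empties, naming the family.
    """
    families = {}
    for i in range(ped.n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s < 0 and d < 0:
            continue
        families.setdefault((s, d), []).append(i)

    changed = True
    while changed:
        changed = False
        for (s, d), kids in families.items():
            sdom = sorted(domains[s]) if s >= 0 else [None]
            ddom = sorted(domains[d]) if d >= 0 else [None]
            sup_s, sup_d = set(), set()
            sup_kids = {c: set() for c in kids}
            for gs in sdom:
                for gd in ddom:
                    kid_support = []
                    for c in kids:
                        ok = {g for g in domains[c] if _child_ok(g, gs, gd)}
                        if not ok:
                            break
                        kid_support.append((c, ok))
                    else:
                        if gs is not None:
                            sup_s.add(gs)
                        if gd is not None:
                            sup_d.add(gd)
                        for c, ok in kid_support:
                            sup_kids[c] |= ok
            for pos, sup in [(s, sup_s), (d, sup_d)] + [
                (c, sup_kids[c]) for c in kids
            ]:
                if pos is None or pos < 0:
                    continue
                if not sup:
                    sire_id = ped.ids[s] if s >= 0 else "<unknown>"
                    dam_id = ped.ids[d] if d >= 0 else "<unknown>"
                    raise MendelianError(
                        f"no Mendelian-consistent {locus} genotypes for family "
                        f"sire={sire_id} dam={dam_id} "
                        f"offspring={[ped.ids[c] for c in kids]}"
                    )
                if sup < domains[pos]:
                    domains[pos] = sup
                    changed = True


def _components(ped: Pedigree):
    """Connected components of the parent-offspring graph (positions)."""
    parent = list(range(ped.n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(ped.n):
        for p in (int(ped.sire[i]), int(ped.dam[i])):
            if p >= 0:
                union(i, p)
    comps = {}
    for i in range(ped.n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _exact_component(ped: Pedigree, domains, members):
    """Exact domain reduction for one small component by enumerating all
    Mendelian-consistent assignments (members are in topological order)."""
    members = sorted(members)
    pos_in = {m: k for k, m in enumerate(members)}
    support = [set() for _ in members]
    assign = [None] * len(members)

    def rec(k):
        if k == len(members):
            for kk, g in enumerate(assign):
                support[kk].add(g)
            return
        m = members[k]
        s, d = int(ped.sire[m]), int(ped.dam[m])
        gs = assign[pos_in[s]] if s >= 0 else None
        gd = assign[pos_in[d]] if d >= 0 else None
        for g in domains[m]:
            if _child_ok(g, gs, gd) if (s >= 0 or d >= 0) else True:
                assign[k] = g
                rec(k + 1)
        assign[k] = None

    rec(0)
    if members and not support[0]:
        raise MendelianError(
            "no Mendelian-consistent genotype assignment for pedigree "
            f"component containing {ped.ids[members[0]]!r}"
        )
    for kk, m in enumerate(members):
        domains[m] = support[kk]


def deduce_genotypes(
    ped: Pedigree,
    colour=None,
    measured: GenotypeTable | None = None,
    exact_max: int = 10,
) -> GenotypeTable:
    """Deduce genotypes from coat colour and measured relatives.

    Parameters
    ----------
    ped : Pedigree
    colour : mapping or Series id -> {grey, coloured, unknown}, optional
        Constrains STX17 only: coloured animals are gg, grey animals are
        not gg.
    measured : GenotypeTable, optional
        Measured genotypes; never overwritten, conflicts raise.
    exact_max : int
        Components with at most this many animals are additionally resolved
        by exhaustive enumeration (exact); larger components rely on
        family-wise elimination alone.

    Returns
    -------
    GenotypeTable with deduced entries flagged ``deduced``.
    """
    measured = measured if measured is not None else GenotypeTable.empty(ped.ids)
    colour = colour if colour is not None else {}

    out = {"id": list(ped.ids)}
    for locus in LOCI:
        domains = [set((0, 1, 2)) for _ in range(ped.n)]
        meas_val = {}
        for i, a in enumerate(ped.ids):
            g = measured.get(a, locus)
            if g != UNKNOWN:
                meas_val[i] = _COUNTS[locus][g]
                domains[i] = {meas_val[i]}
        if locus == "stx17":
            for i, a in enumerate(ped.ids):
                c = colour.get(a, UNKNOWN) if hasattr(colour, "get") else UNKNOWN
                if c == "coloured":
                    domains[i] &= {0}
                    if not domains[i]:
                        raise MendelianError(
                            f"animal {a!r} is coloured but measured "
                            f"{measured.get(a, locus)}"
                        )
                elif c == "grey":
                    domains[i] -= {0}
                    if not domains[i]:
                        raise MendelianError(
                            f"animal {a!r} is grey but measured gg"
                        )

        _eliminate(ped, domains, locus)
        for members in _components(ped):
            if len(members) <= exact_max:
                _exact_component(ped, domains, members)

        vals, srcs = [], []
        for i, a in enumerate(ped.ids):
            if i in meas_val:
                if meas_val[i] not in domains[i]:  # pragma: no cover - guarded above
                    raise MendelianError(
                        f"measured {locus} genotype of {a!r} is inconsistent"
                    )
                vals.append(_LABELS[locus][meas_val[i]])
                srcs.append("measured")
            elif len(domains[i]) == 1:
                vals.append(_LABELS[locus][next(iter(domains[i]))])
                srcs.append("deduced")
            else:
                vals.append(UNKNOWN)
                srcs.append(UNKNOWN)
        out[locus] = vals
        out[f"{locus}_source"] = srcs

    return GenotypeTable(pd.DataFrame(out))


def allele_frequencies(
    gt: GenotypeTable, subset=None, locus: str = "stx17"
) -> AlleleFrequencies:
    """Reference-allele frequency by counting: p = (2 n_homref + n_het) / (2 n)."""
    if locus not in LOCI:
        raise ValueError(f"unknown locus {locus!r}")
    frame = gt.frame
    if subset is not None:
        subset = {str(a) for a in subset}
        if not subset:
            raise ValueError("empty animal subset")
        frame = frame[frame["id"].isin(subset)]
    counts = frame[locus].map(_COUNTS[locus])
    known = counts.dropna()
    if known.empty:
        raise ValueError(f"no known {locus} genotypes in subset")
    p = known.sum() / (2.0 * len(known))
    return AlleleFrequencies(locus=locus, p=float(p), n_counted=int(len(known)))
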
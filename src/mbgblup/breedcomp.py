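"""Pedigree-based breed composition and haplotype breed-of-origin.

The breed-proportion matrix Q assigns every animal the fraction of its
genome expected from each founder breed, computed by recursively averaging
parental proportions through the pedigree (deep pedigrees, depth-capped).
Crossbred reference animals are selected by per-breed proportion
thresholds, and each parental haplotype is labelled with its parent's
breed when that parent is sufficiently purebred — the eligibility rule for
the gametic, breed-specific-frequency relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_qc import MISSING

UNKNOWN = "unknown"
MIXED = "mixed"

__all__ = [
    "breed_proportions",
    "select_crossbred_reference",
    "assign_haplotype_origin",
    "rule_based_phase",
    "haplotype_counts",
    "UNKNOWN",
    "MIXED",
]


def _pedigree_maps(pedigree: pd.DataFrame):
    sire = dict(zip(pedigree["id"].astype(int), pedigree["sire"].astype(int)))
    dam = dict(zip(pedigree["id"].astype(int), pedigree["dam"].astype(int)))
    return sire, dam


def breed_proportions(
    pedigree: pd.DataFrame,
    founder_breeds: Mapping[int, str] | None = None,
    max_depth: int = 6,
) -> pd.DataFrame:
    """Breed-proportion (Q) row for every animal in the pedigree.

    An animal's proportions are the average of its parents' proportions;
    labelled founders are unit vectors on their breed. Unknown parents and
    ancestors beyond ``max_depth`` generations contribute an ``unknown``
    pseudo-breed so that every row still sums to one.

    Parameters
    ----------
    pedigree
        Columns ``id``, ``sire``, ``dam`` (0 = unknown parent) and, if
        ``founder_breeds`` is not given, a ``breed`` column labelling
        founders.
    founder_breeds
        Optional explicit id -> breed mapping for founders.
    max_depth
        Pedigree depth used, counted in generations above each animal.

    Returns
    -------
    DataFrame indexed by animal id with one column per breed (plus
    ``unknown`` if needed); rows sum to 1.
    """
    sire_of, dam_of = _pedigree_maps(pedigree)
    if founder_breeds is None:
        if "breed" not in pedigree.columns:
            raise ValueError("provide founder_breeds or a 'breed' pedigree column")
        founder_breeds = {
            int(r.id): str(r.breed)
            for r in pedigree.itertuples()
            if isinstance(r.breed, str) and r.breed != ""
        }
    breeds = sorted(set(founder_breeds.values()))
    cols = breeds + [UNKNOWN]
    b_index = {b: i for i, b in enumerate(cols)}
    unknown_vec = np.zeros(len(cols))
    unknown_vec[-1] = 1.0

    cache: dict[tuple[int, int], np.ndarray] = {}
    in_progress: set[int] = set()

    def prop(animal: int, depth: int) -> np.ndarray:
        if animal == 0:
            return unknown_vec
        if animal not in sire_of:
            raise KeyError(f"animal {animal} absent from pedigree")
        if animal in founder_breeds:
            v = np.zeros(len(cols))
            v[b_index[founder_breeds[animal]]] = 1.0
            return v
        if depth >= max_depth:
            return unknown_vec
        key = (animal, depth)
        if key in cache:
            return cache[key]
        if animal in in_progress:
            raise ValueError(f"pedigree cycle detected at animal {animal}")
        in_progress.add(animal)
        v = 0.5 * prop(sire_of[animal], depth + 1) + 0.5 * prop(dam_of[animal], depth + 1)
        in_progress.discard(animal)
        cache[key] = v
        return v

    rows = {int(a): prop(int(a), 0) for a in pedigree["id"]}
    q = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    q.index.name = "id"
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-12):
        raise AssertionError("breed proportions must sum to 1")
    if (q[UNKNOWN] == 0).all():
        q = q.drop(columns=[UNKNOWN])
    return q


def select_crossbred_reference(
    compositions: pd.DataFrame, breed: str, threshold: float
) -> list[int]:
    """Animals eligible for the crossbred reference set of ``breed``.

    Selects animals whose proportion of ``breed`` is at least ``threshold``
    while excluding (near-)purebreds of any *other* breed (proportion of
    another single breed >= 0.999), which can only matter at very low
    thresholds.
    """
    if breed not in compositions.columns:
        raise KeyError(f"unknown breed label {breed!r}")
    sel = compositions[breed] >= threshold
    others = [c for c in compositions.columns if c not in (breed, UNKNOWN)]
    if others:
        sel &= ~(compositions[others] >= 0.999).any(axis=1)
    return [int(a) for a in compositions.index[sel]]


def assign_haplotype_origin(
    pedigree: pd.DataFrame,
    compositions: pd.DataFrame,
    purity_threshold: float = 0.97,
) -> pd.DataFrame:
    """Label each animal's paternal and maternal haplotype with a breed.

    A haplotype is labelled with its parent's majority breed when that
    parent's proportion of the breed exceeds ``purity_threshold``
    (default 0.97), otherwise ``mixed``. Animals with a missing parent get
    ``mixed`` on that side. Animals with any ``mixed`` haplotype are not
    eligible for the gametic breed-specific-frequency relationship matrix.

    Returns a DataFrame indexed by animal id with columns
    ``paternal_breed``, ``maternal_breed``, ``paternal_purity``,
    ``maternal_purity``, ``g2_eligible``.
    """
    cols = [c for c in compositions.columns if c != UNKNOWN]

    def parent_label(parent: int) -> tuple[str, float]:
        if parent == 0 or parent not in compositions.index:
            return MIXED, 0.0
        row = compositions.loc[parent, cols]
        best = str(row.idxmax())
        purity = float(row.max())
        return (best, purity) if purity > purity_threshold else (MIXED, purity)

    out = {}
    for r in pedigree.itertuples():
        pb, pp = parent_label(int(r.sire))
        mb, mp = parent_label(int(r.dam))
        out[int(r.id)] = (pb, mb, pp, mp, pb != MIXED and mb != MIXED)
    df = pd.DataFrame.from_dict(
        out,
        orient="index",
        columns=[
            "paternal_breed",
            "maternal_breed",
            "paternal_purity",
            "maternal_purity",
            "g2_eligible",
        ],
    )
    df.index.name = "id"
    return df


def haplotype_counts(compositions: pd.DataFrame, animals: Sequence[int]) -> pd.Series:
    """Breed haplotype count of a reference set: 2 x set size x mean breed
    proportion, the standard accounting for how many gametes of each breed
    a (cross)bred reference contributes."""
    sub = compositions.loc[list(animals)]
    return 2 * len(sub) * sub.mean(axis=0)


def rule_based_phase(
    genotypes: np.ndarray,
    animal_ids: Sequence[int],
    pedigree: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Partial pedigree-based phasing of 0/1/2 genotypes into parental
    gametes.

    For each animal with both parents genotyped, loci are resolved by
    trio logic: a homozygous offspring determines both transmitted
    alleles; a heterozygous offspring is resolved when at least one parent
    is homozygous (the homozygous parent's allele is assigned to that
    side). Heterozygous offspring of double-heterozygous matings stay
    unresolved; Mendelian-inconsistent loci are set unresolved and
    counted.

    Parameters
    ----------
    genotypes
        (n, L) second-allele counts; missing calls (negative) stay
        unresolved.
    animal_ids
        Animal id per genotype row.
    pedigree
        ``id``, ``sire``, ``dam`` (0 = unknown).

    Returns
    -------
    phased
        (n, 2, L) int8 array of alleles, slot 0 paternal, -1 unresolved.
    stats
        Per-animal resolution fraction and Mendelian-error count.
    """
    geno = np.asarray(genotypes)
    n, L = geno.shape
    row = {int(a): i for i, a in enumerate(animal_ids)}
    sire_of, dam_of = _pedigree_maps(pedigree)
    phased = np.full((n, 2, L), MISSING, dtype=np.int8)
    stats = []

    for aid, i in row.items():
        g = geno[i]
        s, d = sire_of.get(aid, 0), dam_of.get(aid, 0)
        gs = geno[row[s]] if s in row else None
        gd = geno[row[d]] if d in row else None
        pat = np.full(L, MISSING, dtype=np.int8)
        mat = np.full(L, MISSING, dtype=np.int8)
        valid = g >= 0
        # homozygous offspring: both gametes known
        hom0 = valid & (g == 0)
        hom2 = valid & (g == 2)
        pat[hom0] = mat[hom0] = 0
        pat[hom2] = mat[hom2] = 1
        het = valid & (g == 1)
        n_err = 0
        if gs is not None and gd is not None:
            s_hom0, s_hom2 = gs == 0, gs == 2
            d_hom0, d_hom2 = gd == 0, gd == 2
            # het offspring, homozygous sire: paternal allele forced
            pat[het & s_hom0] = 0
            mat[het & s_hom0] = 1
            pat[het & s_hom2] = 1
            mat[het & s_hom2] = 0
            # het offspring, homozygous dam (where sire did not resolve it)
            left = het & (pat == MISSING)
            mat[left & d_hom0] = 0
            pat[left & d_hom0] = 1
            mat[left & d_hom2] = 1
            pat[left & d_hom2] = 0
            # Mendelian checks: offspring allele impossible given a parent
            err = (
                (hom0 & (s_hom2 | d_hom2))
                | (hom2 & (s_hom0 | d_hom0))
                | (het & s_hom0 & d_hom0)
                | (het & s_hom2 & d_hom2)
            )
            n_err = int(err.sum())
            pat[err] = mat[err] = MISSING
        phased[i, 0] = pat
        phased[i, 1] = mat
        resolved = float(((pat != MISSING) & (mat != MISSING)).mean())
        stats.append((aid, resolved, n_err))

    stats_df = pd.DataFrame(stats, columns=["id", "resolved_fraction", "mendel_errors"])
    return phased, stats_df.set_index("id")
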
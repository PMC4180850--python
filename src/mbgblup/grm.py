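"""Genomic relationship matrices: genotype-based (G1) and gametic,
breed-specific-frequency (G2), with diagnostics.

G1 is the standard allele-frequency-centred matrix

    G1 = Z Z' / (2 * sum_j p_j (1 - p_j)),   Z_ij = M_ij - 2 p_j,

with M the 0/1/2 second-allele count and p_j the observed frequency in the
reference set. G2 is a gametic variant for multi-breed data: each parental
haplotype (0/1 alleles) is centred by the allele frequency of *its own
breed of origin*,

    G2_i = Z_i Z_i' / sum_j p_j (1 - p_j),   Z_i,aj = H_aj - p_{b(a),j},

separately for the paternal (i = 1) and maternal (i = 2) gametes, and
G2 = (G2_1 + G2_2) / 2. Because several breeds can contribute haplotypes
to the same gametic matrix, the denominator uses the haplotype-count-
weighted average of each breed's sum of p(1-p), with loci monomorphic
within a breed excluded from that breed's sum; the choice is recorded in
the matrix metadata. The cross-gamete products are deliberately omitted
(an optional "full gametic" variant includes them for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_qc import GenotypeTable

__all__ = [
    "GRMatrix",
    "allele_frequencies",
    "breed_allele_frequencies",
    "build_g1",
    "build_g2",
    "grm_element_correlation",
    "grm_pca",
    "haplotype_group_relationship",
]


@dataclass
class GRMatrix:
    """A symmetric animal-by-animal genomic relationship matrix."""

    animal_ids: list
    values: np.ndarray
    flavor: str  # "G1" | "G2"
    denominator: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if v.shape[0] != len(self.animal_ids):
            raise ValueError("GRM dimension must equal the number of animals")
        if not np.isfinite(v).all():
            raise ValueError("GRM has non-finite entries")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("GRM must be symmetric within 1e-12")
        self.values = (v + v.T) / 2

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def reorder(self, animal_ids: Sequence) -> "GRMatrix":
        idx = [self.animal_ids.index(a) for a in animal_ids]
        return GRMatrix(
            [self.animal_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.flavor,
            self.denominator,
            dict(self.meta),
        )


def _dosage_matrix(table: GenotypeTable | np.ndarray) -> np.ndarray:
    if isinstance(table, GenotypeTable):
        d = table.dosage()
    else:
        d = np.asarray(table, dtype=float)
    if np.isnan(d).any():
        raise ValueError("impute missing calls before building a GRM")
    return d


def allele_frequencies(
    table: GenotypeTable, subset: Sequence[int] | None = None
) -> np.ndarray:
    """Observed second-allele frequency per SNP: mean dosage / 2 over
    non-missing calls of the given animal rows (default: all)."""
    d = table.dosage()
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty subset")
        d = d[np.asarray(subset)]
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("SNP with no calls in the requested subset")
    return np.nanmean(d, axis=0) / 2


def breed_allele_frequencies(
    haplotypes: np.ndarray, origins: Sequence[str]
) -> pd.DataFrame:
    """Per-breed second-allele frequencies from breed-labelled gametes.

    ``haplotypes`` is (n_animals, 2, L) with 0/1 alleles; ``origins`` is a
    flat sequence of 2*n breed labels ordered (animal0-paternal,
    animal0-maternal, animal1-paternal, ...). Haplotypes labelled
    ``mixed`` are ignored. Raises if a breed ends up with no haplotypes.
    """
    h = np.asarray(haplotypes)
    flat = h.reshape(-1, h.shape[-1]).astype(float)
    labels = np.asarray(list(origins))
    if len(labels) != flat.shape[0]:
        raise ValueError("need one breed label per gamete (2 per animal)")
    breeds = sorted({b for b in labels if b != "mixed"})
    rows = {}
    for b in breeds:
        sel = labels == b
        if not sel.any():
            raise ValueError(f"breed {b} has zero labelled haplotypes")
        rows[b] = flat[sel].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def build_g1(
    table: GenotypeTable | np.ndarray,
    freqs: np.ndarray,
    animal_ids: Sequence | None = None,
) -> GRMatrix:
    """Genotype-based genomic relationship matrix.

    Centres the 0/1/2 dosage matrix by twice the supplied allele
    frequencies and scales by the single shared denominator
    ``2 * sum_j p_j (1 - p_j)``. Frequencies must be strictly inside
    (0, 1): monomorphic SNPs should have been filtered.
    """
    m = _dosage_matrix(table)
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must be strictly in (0,1); filter first")
    z = m - 2 * p
    denom = 2 * float((p * (1 - p)).sum())
    g = z @ z.T / denom
    if animal_ids is None:
        animal_ids = (
            list(table.animal_ids)
            if isinstance(table, GenotypeTable)
            else list(range(m.shape[0]))
        )
    return GRMatrix(list(animal_ids), g, "G1", denom, {"n_snps": m.shape[1]})


def _gametic_denominator(
    breed_freqs: pd.DataFrame, origin_labels: np.ndarray
) -> tuple[float, dict]:
    """Haplotype-count-weighted average of per-breed sum of p(1-p), with
    within-breed monomorphic loci excluded from that breed's sum."""
    counts = pd.Series(origin_labels).value_counts()
    total = 0.0
    weights = 0
    per_breed = {}
    for b, k in counts.items():
        p = breed_freqs.loc[b].to_numpy()
        poly = (p > 0) & (p < 1)
        s = float((p[poly] * (1 - p[poly])).sum())
        per_breed[b] = s
        total += k * s
        weights += k
    return total / weights, per_breed


def build_g2(
    haplotypes: np.ndarray,
    origins: pd.DataFrame,
    breed_freqs: pd.DataFrame,
    animal_ids: Sequence | None = None,
    full_gametic: bool = False,
) -> GRMatrix:
    """Gametic genomic relationship matrix with breed-of-origin
    allele frequencies.

    Parameters
    ----------
    haplotypes
        (n, 2, L) phased 0/1 alleles; slot 0 paternal, slot 1 maternal.
    origins
        DataFrame (one row per animal, aligned with ``haplotypes``) with
        ``paternal_breed`` and ``maternal_breed`` columns; every label
        must be a real breed (``mixed`` animals are ineligible and must be
        excluded beforehand).
    breed_freqs
        Breed x SNP frequency table (from
        :func:`breed_allele_frequencies` or simulator truth).
    full_gametic
        Include the paternal-maternal cross products (off by default; the
        default matches the printed two-term average of the paternal and
        maternal gametic matrices).
    """
    h = np.asarray(haplotypes, dtype=float)
    n = h.shape[0]
    pat_lab = origins["paternal_breed"].to_numpy()
    mat_lab = origins["maternal_breed"].to_numpy()
    bad = [i for i in range(n) if pat_lab[i] == "mixed" or mat_lab[i] == "mixed"]
    if bad:
        ids = [animal_ids[i] if animal_ids is not None else i for i in bad]
        raise ValueError(f"unlabelled (mixed) haplotypes for animals: {ids[:10]}")
    missing = (set(pat_lab) | set(mat_lab)) - set(breed_freqs.index)
    if missing:
        raise ValueError(f"no allele frequencies for breeds: {sorted(missing)}")

    fp = breed_freqs.loc[list(pat_lab)].to_numpy()
    fm = breed_freqs.loc[list(mat_lab)].to_numpy()
    z1 = h[:, 0, :] - fp
    z2 = h[:, 1, :] - fm

    d1, per1 = _gametic_denominator(breed_freqs, pat_lab)
    d2, per2 = _gametic_denominator(breed_freqs, mat_lab)
    g21 = z1 @ z1.T / d1
    g22 = z2 @ z2.T / d2
    if full_gametic:
        cross = (z1 @ z2.T) / np.sqrt(d1 * d2)
        g = (g21 + g22 + cross + cross.T) / 2
    else:
        g = (g21 + g22) / 2
    if animal_ids is None:
        animal_ids = list(range(n))
    return GRMatrix(
        list(animal_ids),
        g,
        "G2",
        (d1 + d2) / 2,
        {
            "denominator_paternal": d1,
            "denominator_maternal": d2,
            "per_breed_sum_pq_paternal": per1,
            "per_breed_sum_pq_maternal": per2,
            "full_gametic": full_gametic,
            "n_snps": h.shape[2],
        },
    )


def grm_element_correlation(
    a: GRMatrix, b: GRMatrix, include_diagonal: bool = False
) -> float:
    """Pearson correlation between the elements of two GRMs over the same
    animals (upper triangle; diagonal excluded by default)."""
    if a.n != b.n:
        raise ValueError("GRM dimension mismatch")
    if list(a.animal_ids) != list(b.animal_ids):
        raise ValueError("GRMs must be over the same animals in the same order")
    iu = np.triu_indices(a.n, k=0 if include_diagonal else 1)
    return float(np.corrcoef(a.values[iu], b.values[iu])[0, 1])


def grm_pca(
    g: GRMatrix, labels: Sequence[str] | None = None, n_components: int = 2
) -> dict:
    """Principal components of a GRM with an optional breed-cluster purity.

    Eigendecomposes the (symmetric) GRM; component scores are the
    eigenvectors scaled by the square root of their eigenvalues. When
    breed labels are supplied, k-means with one cluster per label is run
    on the leading components and the purity (fraction of animals whose
    cluster's majority label matches their own) plus per-label centroids
    are reported. A spectrum with no variation across the leading
    components is reported as degenerate with purity NaN.
    """
    vals = np.asarray(g.values)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite GRM")
    evals, evecs = np.linalg.eigh(vals)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = np.clip(evals[:n_components], 0, None)
    scores = evecs[:, :n_components] * np.sqrt(top)
    total = float(np.clip(evals, 0, None).sum())
    shares = top / total if total > 0 else np.zeros_like(top)
    out = {
        "scores": scores,
        "eigenvalues": evals,
        "variance_shares": shares,
        "animal_ids": list(g.animal_ids),
    }
    if labels is not None:
        labels = np.asarray(list(labels))
        k = len(np.unique(labels))
        isotropic = np.isclose(evals.max(), evals.min())
        if isotropic or np.allclose(scores.std(axis=0), 0):
            # an isotropic spectrum carries no clustering information
            out["purity"] = float("nan")
            out["degenerate"] = True
            return out
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(scores)
        purity = 0
        for c in range(k):
            members = labels[km.labels_ == c]
            if len(members):
                purity += pd.Series(members).value_counts().iloc[0]
        out["purity"] = purity / len(labels)
        out["centroids"] = {
            lab: scores[labels == lab].mean(axis=0) for lab in np.unique(labels)
        }
        out["degenerate"] = False
    return out


def plot_pca(pca: dict, labels: Sequence[str], path) -> None:
    """Scatter PC1 vs PC2 coloured by breed (the classic multi-breed GRM
    diagnostic). ``pca`` is the output of :func:`grm_pca`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = pca["scores"]
    labels = np.asarray(list(labels))
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(scores[sel, 0], scores[sel, 1], s=12, label=str(lab))
    shares = pca.get("variance_shares", [np.nan, np.nan])
    ax.set_xlabel(f"PC1 ({100 * shares[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * shares[1]:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_allele_frequency_comparison(freqs_a, freqs_b, names: tuple[str, str], path) -> None:
    """Scatter of per-SNP allele frequencies in one breed against another,
    showing how far marker frequencies diverge between breeds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(np.asarray(freqs_a), np.asarray(freqs_b), s=4, alpha=0.4)
    ax.plot([0, 1], [0, 1], lw=0.8, color="k")
    ax.set_xlabel(f"{names[0]} allele frequency")
    ax.set_ylabel(f"{names[1]} allele frequency")
    r = float(np.corrcoef(freqs_a, freqs_b)[0, 1])
    ax.set_title(f"r = {r:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def haplotype_group_relationship(
    haplotypes: np.ndarray,
    breed_freqs: pd.DataFrame,
    group_a: Sequence[tuple[int, int, str]],
    group_b_rows: Sequence[int],
    group_b_origins: pd.DataFrame | None = None,
    pooled_freqs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean and SD of gametic relationships between a haplotype class and
    an animal set.

    ``group_a`` lists (animal_row, gamete_slot, breed_label) triples — for
    example all paternal gametes of one breed. Each such gamete is centred
    by its breed's frequencies; each group-b animal is represented by the
    average of its two centred gametes (centred by ``group_b_origins``
    breed labels when given, else by ``pooled_freqs``). Elements are
    scaled by the group-a gametic denominator so values are on the G2
    scale.
    """
    if len(group_a) == 0 or len(group_b_rows) == 0:
        raise ValueError("empty group")
    h = np.asarray(haplotypes, dtype=float)
    a_lab = np.asarray([t[2] for t in group_a])
    za = np.stack(
        [h[r, s, :] - breed_freqs.loc[lab].to_numpy() for r, s, lab in group_a]
    )
    rows_b = np.asarray(group_b_rows)
    if group_b_origins is not None:
        fp = breed_freqs.loc[group_b_origins["paternal_breed"].to_numpy()].to_numpy()
        fm = breed_freqs.loc[group_b_origins["maternal_breed"].to_numpy()].to_numpy()
    elif pooled_freqs is not None:
        fp = fm = np.asarray(pooled_freqs)
    else:
        raise ValueError("supply group_b_origins or pooled_freqs")
    zb = ((h[rows_b, 0, :] - fp) + (h[rows_b, 1, :] - fm)) / 2
    denom, _ = _gametic_denominator(breed_freqs, a_lab)
    rel = za @ zb.T / denom
    return float(rel.mean()), float(rel.std())
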
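"""Scenario runner: the full purebred / crossbred / combined comparison.

Drives one simulated multi-breed study end to end — simulation, phenotype
trimming, genotype QC and imputation, pedigree breed proportions,
genotype-based (G1) and gametic breed-specific-frequency (G2)
relationship matrices, GBLUP, and validation accuracy per breed — for a
set of nested reference designs (growing purebred references of the focal
breed, a crossbred-only reference, and their combination), over replicate
seeds.

The default "sheep-like" preset keeps the real study's design ratios at
desk scale: purebred focal references of 200/400/600 animals, a
400-animal F1 crossbred reference whose focal haplotype count matches the
smallest purebred reference, progeny-tested validation sires per breed
with industry-like reliability floors, and both GRM flavors.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import breedcomp, evaluation, geno_qc, grm, popsim
from .gblup import ModelSpec, build_design_matrices, solve_mme
from .io import write_json

__all__ = [
    "DesignDef",
    "ScenarioConfig",
    "ScenarioResult",
    "sheep_like_scenario",
    "run_scenario",
    "aggregate_accuracies",
]


@dataclass(frozen=True)
class DesignDef:
    """One reference population design: how many focal-breed purebred
    records and whether the crossbred cohort is included."""

    name: str
    n_purebred: int = 0
    include_crossbred: bool = False


@dataclass
class ScenarioConfig:
    sim: popsim.SimConfig = field(default_factory=popsim.SimConfig)
    seeds: tuple[int, ...] = (1,)
    focal_breed: str = "MER"
    cross_sire_breed: str = "BL"
    n_crossbred: int = 400
    designs: tuple[DesignDef, ...] = (
        DesignDef("pure200", 200),
        DesignDef("pure400", 400),
        DesignDef("pure600", 600),
        DesignDef("cross400", 0, True),
        DesignDef("cross400+pure600", 600, True),
    )
    n_sires: Mapping[str, int] = field(
        default_factory=lambda: {"MER": 20, "BL": 15, "PD": 5, "WS": 5}
    )
    validation_counts: Mapping[str, int] = field(
        default_factory=lambda: {"MER": 35, "BL": 11, "PD": 14, "WS": 28}
    )
    reliability_floors: Mapping[str, float] = field(
        default_factory=lambda: {"WS": 0.64, "default": 0.70}
    )
    crossbred_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"BL": 0.45, "PD": 0.45, "WS": 0.35}
    )
    grm_flavors: tuple[str, ...] = ("G1", "G2")
    n_focal_dams: int = 500  # research-ewe generation size for the focal breed
    missing_call_fraction: float = 0.002
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.designs:
            raise ValueError("at least one reference design is required")
        names = [d.name for d in self.designs]
        if len(set(names)) != len(names):
            raise ValueError("design names must be unique")
        known = set(self.sim.breed_names)
        for b in list(self.validation_counts) + [self.focal_breed, self.cross_sire_breed]:
            if b not in known:
                raise ValueError(f"breed {b!r} not in the simulation config")

    def floor(self, breed: str) -> float:
        return self.reliability_floors.get(breed, self.reliability_floors["default"])


def sheep_like_scenario(
    seeds: Sequence[int] = (1,), **overrides
) -> ScenarioConfig:
    """The scaled-down default comparison (see module docstring)."""
    return ScenarioConfig(seeds=tuple(int(s) for s in seeds), **overrides)


@dataclass
class ScenarioResult:
    accuracies: pd.DataFrame  # seed, design, flavor, breed, n, accuracy
    diagnostics: pd.DataFrame  # per-seed scalars
    summary: pd.DataFrame  # design x (breed, flavor) table with letters
    manifest: dict
    failures: list[dict] = field(default_factory=list)


def _config_digest(cfg: ScenarioConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_seed(cfg: ScenarioConfig, seed: int):
    sim = replace(cfg.sim, seed=int(seed))
    base = popsim.simulate_founders(sim)
    breeds = popsim.derive_breeds(base, sim)
    breeds.qtl = popsim.sample_qtl(breeds, sim)
    max_pure = max((d.n_purebred for d in cfg.designs), default=0)
    any_cross = any(d.include_crossbred for d in cfg.designs)
    design = popsim.DesignSpec(
        n_purebred={cfg.focal_breed: max_pure} if max_pure else {},
        f1_crosses=(
            [(cfg.cross_sire_breed, cfg.focal_breed, cfg.n_crossbred)]
            if any_cross
            else []
        ),
        n_sires=dict(cfg.n_sires),
        validation_sires=dict(cfg.validation_counts),
        n_dams={cfg.focal_breed: cfg.n_focal_dams} if cfg.n_focal_dams else {},
    )
    pop = popsim.build_design(breeds, sim, design)
    pop.qtl = breeds.qtl
    records = popsim.simulate_phenotypes(pop, sim, seed=seed)
    records, _trimmed = geno_qc.trim_phenotype_outliers(records, "y", 4.0)
    return sim, pop, records


def run_seed(cfg: ScenarioConfig, seed: int) -> dict:
    """Run every design x GRM-flavor cell for one seed.

    Returns accuracy rows, per-seed diagnostics (QC counts, G1-G2 element
    correlation on the combined reference, PCA purity over the validation
    sires) and failure records for cells that aborted.
    """
    sim, pop, records = _simulate_seed(cfg, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))

    val_ids = {b: list(v) for b, v in pop.validation_sires.items()}
    all_val = [a for ids in val_ids.values() for a in ids]
    record_ids = records["id"].tolist()
    used_ids = sorted(set(record_ids) | set(all_val))

    # genotype QC on the animals the analysis touches
    table = popsim.genotype_table(pop, animal_rows=pop.rows(used_ids))
    if cfg.missing_call_fraction > 0:
        mask = rng.random(table.calls.shape) < cfg.missing_call_fraction
        table.calls[mask] = geno_qc.MISSING
    table, snp_report = geno_qc.qc_snps(table)
    table, sample_report = geno_qc.qc_samples(table)
    imputed = geno_qc.impute_missing(table)
    kept_loci = table.snps["locus"].to_numpy()
    row_of = {a: i for i, a in enumerate(table.animal_ids)}
    kept_animals = set(table.animal_ids)
    records = records[records["id"].astype(str).isin(kept_animals)]

    # pedigree breed proportions; gamete origins from simulator truth
    # (the pedigree-based rule cannot label founders, whose parents are
    # unrecorded — truth phase is the default pathway for G2)
    Q = breedcomp.breed_proportions(pop.pedigree, max_depth=6)
    origins = popsim.true_haplotype_origins(pop)
    haps = pop.haplotypes[:, :, kept_loci]

    cohorts = dict(zip(pop.pedigree["id"], pop.pedigree["cohort"]))
    pure_pool = [a for a in record_ids if cohorts[a].startswith("purebred_")
                 and str(a) in kept_animals]
    cross_cohort = f"f1_{cfg.cross_sire_breed}_{cfg.focal_breed}"
    cross_all = [a for a in record_ids if cohorts[a] == cross_cohort
                 and str(a) in kept_animals]
    cross_pool = breedcomp.select_crossbred_reference(
        Q.loc[cross_all], cfg.cross_sire_breed,
        cfg.crossbred_thresholds.get(cfg.cross_sire_breed, 0.45),
    ) if cross_all else []

    # validation EBVs from simulated progeny tests
    tbv_all = popsim.true_breeding_values(pop)
    ebv: dict[str, pd.DataFrame] = {}
    for b, ids in val_ids.items():
        rel = popsim.draw_validation_reliabilities(len(ids), cfg.floor(b), rng)
        salt = sum(ord(c) for c in b)  # stable across processes
        ebv[b] = popsim.simulate_progeny_test_ebv(
            tbv_all[pop.rows(ids)], rel, seed=seed * 1000 + salt, animal_ids=ids
        )

    vc = {
        "additive": sim.trait_h2 * sim.trait_sd**2,
        "maternal": sim.maternal_variance_ratio * sim.trait_sd**2,
        "sire_flock": sim.sire_flock_variance_ratio * sim.trait_sd**2,
        "residual": (
            1 - sim.trait_h2 - sim.maternal_variance_ratio - sim.sire_flock_variance_ratio
        )
        * sim.trait_sd**2,
    }
    other_breeds = [b for b in sim.breed_names if b != cfg.focal_breed]
    spec = ModelSpec(breed_covariates=other_breeds, variance_components=vc)

    acc_rows, failures = [], []
    combined_grms: dict[str, grm.GRMatrix] = {}
    for design in cfg.designs:
        ref_ids = list(pure_pool[: design.n_purebred])
        if design.include_crossbred:
            ref_ids += list(cross_pool)
        if not ref_ids:
            failures.append({"seed": seed, "design": design.name,
                             "reason": "empty reference set"})
            continue
        g_ids = ref_ids + [a for a in all_val if a not in set(ref_ids)]
        rows = np.array([row_of[str(a)] for a in g_ids])
        rec = records[records["id"].isin(set(ref_ids))]
        for flavor in cfg.grm_flavors:
            try:
                if flavor == "G1":
                    ref_rows = np.array([row_of[str(a)] for a in ref_ids])
                    freqs = grm.allele_frequencies(imputed, ref_rows)
                    eps = 1 / (4 * len(ref_ids))
                    freqs = np.clip(freqs, eps, 1 - eps)
                    gmat = grm.build_g1(imputed.calls[rows], freqs, g_ids)
                elif flavor == "G2":
                    sub_or = origins.loc[g_ids]
                    if not sub_or["g2_eligible"].all():
                        raise ValueError("G2-ineligible animals in reference")
                    h_sub = haps[pop.rows(g_ids)]
                    labels = np.column_stack(
                        [sub_or["paternal_breed"], sub_or["maternal_breed"]]
                    ).ravel()
                    bfreq = grm.breed_allele_frequencies(h_sub, labels)
                    eps = 1 / (4 * len(g_ids))
                    bfreq = bfreq.clip(eps, 1 - eps)
                    gmat = grm.build_g2(h_sub, sub_or, bfreq, g_ids)
                else:
                    raise ValueError(f"unknown GRM flavor {flavor}")
                dm = build_design_matrices(rec, spec, Q=Q, g_ids=g_ids)
                fit = solve_mme(dm, gmat, vc, compute_pev=False)
                for b, ids in val_ids.items():
                    res = evaluation.accuracy(
                        fit.gbv.loc[ids].to_numpy(),
                        ebv[b].set_index("animal").loc[ids, "ebv"].to_numpy(),
                        breed=b,
                        reference_description=design.name,
                        grm_flavor=flavor,
                    )
                    acc_rows.append(
                        {
                            "seed": seed,
                            "design": design.name,
                            "flavor": flavor,
                            "breed": b,
                            "n": res.n_validation,
                            "accuracy": res.correlation,
                            "n_reference": len(ref_ids),
                        }
                    )
                if design.include_crossbred and design.n_purebred > 0:
                    combined_grms[flavor] = gmat
            except Exception as err:  # keep other cells alive
                failures.append(
                    {"seed": seed, "design": design.name, "flavor": flavor,
                     "reason": repr(err)}
                )

    diag = {
        "seed": seed,
        "n_snps_before": snp_report.n_snps_before,
        "n_snps_after": snp_report.n_snps_after,
        "n_samples_removed": len(sample_report.sample_removals),
        "n_records": len(records),
    }
    if {"G1", "G2"} <= set(combined_grms):
        diag["g1_g2_element_correlation"] = grm.grm_element_correlation(
            combined_grms["G1"], combined_grms["G2"]
        )
    # PCA over the validation sires of all breeds (their own frequencies)
    val_rows = np.array([row_of[str(a)] for a in all_val])
    vf = grm.allele_frequencies(imputed, val_rows)
    eps = 1 / (4 * len(all_val))
    g_val = grm.build_g1(imputed.calls[val_rows], np.clip(vf, eps, 1 - eps), all_val)
    labels = [b for b, ids in val_ids.items() for _ in ids]
    pca = grm.grm_pca(g_val, labels)
    diag["pca_purity"] = pca["purity"]
    for lab, c in pca.get("centroids", {}).items():
        diag[f"pc1_{lab}"] = float(c[0])
        diag[f"pc2_{lab}"] = float(c[1])
    return {"accuracies": acc_rows, "diagnostics": diag, "failures": failures,
            "pca": pca}


def aggregate_accuracies(acc: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy (and its standard error over seeds) per design,
    flavor and breed."""
    grp = acc.groupby(["design", "flavor", "breed"])["accuracy"]
    out = grp.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Run all seeds of a scenario and summarize.

    Any failed cell is recorded with its reason and the remaining cells
    continue. When ``cfg.output_dir`` is set, per-cell accuracies, the
    aggregate table, a Markdown/TSV summary and a manifest (config digest
    plus seeds) are written there.
    """
    acc_rows, diag_rows, failures = [], [], []
    for seed in cfg.seeds:
        out = run_seed(cfg, seed)
        acc_rows += out["accuracies"]
        diag_rows.append(out["diagnostics"])
        failures += out["failures"]
    acc = pd.DataFrame(acc_rows)
    diag = pd.DataFrame(diag_rows)

    agg = aggregate_accuracies(acc) if len(acc) else pd.DataFrame()
    results = []
    for _, r in agg.iterrows():
        sel = (
            (acc["design"] == r["design"])
            & (acc["flavor"] == r["flavor"])
            & (acc["breed"] == r["breed"])
        )
        n_val = int(acc.loc[sel, "n"].iloc[0])
        results.append(
            evaluation.AccuracyResult(
                breed=r["breed"],
                n_validation=max(n_val, 4),
                correlation=float(r["mean"]),
                reference_description=r["design"],
                grm_flavor=r["flavor"],
            )
        )
    summary = evaluation.summarize_scenarios(results) if results else pd.DataFrame()

    manifest = {
        "config_digest": _config_digest(cfg),
        "seeds": list(cfg.seeds),
        "designs": [d.name for d in cfg.designs],
        "n_failures": len(failures),
    }
    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        acc.to_csv(outdir / "accuracies.csv", index=False)
        agg.to_csv(outdir / "accuracy_summary.csv", index=False)
        diag.to_csv(outdir / "diagnostics.csv", index=False)
        summary.to_csv(outdir / "summary_table.tsv", sep="\t")
        with open(outdir / "summary_table.md", "w") as fh:
            fh.write(summary.to_markdown())
        write_json(manifest, outdir / "manifest.json")
        write_json(failures, outdir / "failures.json")
    return ScenarioResult(acc, diag, summary, manifest, failures)
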
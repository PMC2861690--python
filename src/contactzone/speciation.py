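"""Inference layer: phi goodness-of-fit between genetic clusters and the
categories predicted by competing speciation models, plus the per-transect
report assembling every stage of the pipeline.

Under allopatric speciation, genetic clusters should coincide with the
categories defined by the modal mtDNA lineage of each site (the relic of
past geographic isolation); under ecological speciation they should
coincide with habitat categories defined by the ecotone.  The fit of each
model is the phi coefficient sqrt(chi2 / n) of the 2x2 cluster-by-category
table: phi approaches 1 under complete isolation and 0 under free exchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import stats

from .datamodel import TransectDataset
from .differentiation import amova, mean_boundary_fst_std
from .phenotype import (
    HabitatPartition,
    climate_pca,
    cva_traits,
    ecotone_is_real,
    ecotone_partition,
    site_correlation,
)
from .rflp import lineage_site_frequencies
from .structure import (
    McmcConfig,
    align_runs,
    allele_freq_pca,
    hard_assignments,
    run_replicates,
    select_k,
    site_cluster_frequencies,
)


@dataclass
class ContingencyTable2x2:
    """Counts: rows = genetic cluster (or site block), columns = predicted
    category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.n < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


@dataclass
class PhiResult:
    chi2: float | None
    phi: float | None
    p: float | None
    n: int
    degenerate: bool


@dataclass
class SpeciationTest:
    model: str                 # allopatric | ecological | geology_lineage
    table: ContingencyTable2x2
    chi2: float | None
    phi: float | None
    p: float | None
    n: int
    k_used: int | None = None
    forced_k: bool = False
    degenerate: bool = False


def phi_fit(table: ContingencyTable2x2) -> PhiResult:
    """Pearson chi-square (no continuity correction), phi = sqrt(chi2/n),
    and the asymptotic 1-df p.  A zero marginal yields a degenerate result
    rather than an exception."""
    r1, r2, c1, c2 = table.marginals
    n = table.n
    if min(r1, r2, c1, c2) == 0:
        return PhiResult(None, None, None, n, degenerate=True)
    det = table.a * table.d - table.b * table.c
    chi2 = n * det * det / (r1 * r2 * c1 * c2)
    phi = float(np.sqrt(chi2 / n))
    p = float(stats.chi2.sf(chi2, df=1))
    return PhiResult(float(chi2), phi, p, n, degenerate=False)


def assign_categories(dataset: TransectDataset, model: str,
                      partition: HabitatPartition | None = None,
                      geological_boundary: float | None = None
                      ) -> tuple[dict[str, str], int]:
    """Per-individual category predicted by a speciation model.

    Every individual inherits its site's category.  ``allopatric`` uses the
    modal mtDNA lineage of the site (tied sites excluded, count returned);
    ``ecological`` uses the habitat side of the ecotone; ``geology`` uses
    the declared geological boundary position between two adjacent sites.
    """
    gt = dataset.genotypes
    excluded = 0
    site_category: dict[str, str] = {}
    if model == "allopatric":
        freqs = lineage_site_frequencies(dataset)
        for site, row in freqs.iterrows():
            if row["empty"] or row["tie"]:
                continue
            site_category[site] = str(row["mode"])
    elif model == "ecological":
        if partition is None:
            raise ValueError("ecological model requires a HabitatPartition")
        if partition.no_ecotone:
            raise ValueError("ecological model not applicable: no ecotone")
        site_category = {s: str(partition.labels[s]) for s in dataset.site_ids}
    elif model == "geology":
        if geological_boundary is None:
            raise ValueError("geology model requires a boundary position")
        for s in dataset.sites:
            site_category[s.site_id] = (
                "west" if s.position < geological_boundary else "east"
            )
    else:
        raise ValueError(f"unknown model {model!r}")

    out: dict[str, str] = {}
    for ind in gt.individual_ids:
        site = gt.site_of[ind]
        if site in site_category:
            out[ind] = site_category[site]
        else:
            excluded += 1
    if len(set(out.values())) > 2:
        raise ValueError("category labels must be binary per transect")
    return out, excluded


def _crosstab(cluster_of: Mapping[str, int], category_of: Mapping[str, str]
              ) -> ContingencyTable2x2:
    shared = [i for i in cluster_of if i in category_of]
    cats = sorted(set(category_of[i] for i in shared))
    if len(cats) == 1:
        cats = cats + ["__none__"]
    counts = np.zeros((2, 2), dtype=int)
    for i in shared:
        counts[int(cluster_of[i]), cats.index(category_of[i])] += 1
    # record the orientation maximizing the main diagonal (reporting only;
    # phi is invariant under column swap)
    if counts[0, 0] + counts[1, 1] < counts[0, 1] + counts[1, 0]:
        counts = counts[:, ::-1]
    return ContingencyTable2x2(*(int(v) for v in counts.ravel()))


def test_speciation(dataset: TransectDataset, cluster_of: Mapping[str, int],
                    model: str, partition: HabitatPartition | None = None,
                    geological_boundary: float | None = None,
                    k_used: int | None = None, forced_k: bool = False
                    ) -> SpeciationTest:
    """phi goodness of fit between a binary cluster assignment and the
    categories a speciation model predicts."""
    category_of, _ = assign_categories(
        dataset, model, partition=partition,
        geological_boundary=geological_boundary,
    )
    table = _crosstab(cluster_of, category_of)
    res = phi_fit(table)
    return SpeciationTest(
        model=model, table=table, chi2=res.chi2, phi=res.phi, p=res.p,
        n=res.n, k_used=k_used, forced_k=forced_k, degenerate=res.degenerate,
    )


def geology_lineage_fit(dataset: TransectDataset,
                        geological_boundary: float) -> SpeciationTest:
    """phi between the geological side of each site and the mtDNA lineage of
    its individuals (the classic test of lineage/precursor concordance)."""
    category_of, _ = assign_categories(
        dataset, "geology", geological_boundary=geological_boundary
    )
    lineages = sorted(set(dataset.mtdna_lineage.values()))
    if len(lineages) > 2:
        raise ValueError("geology/lineage fit needs a binary lineage set")
    lineage_idx = {lab: i for i, lab in enumerate(lineages)}
    cluster_of = {
        ind: lineage_idx[lab]
        for ind, lab in dataset.mtdna_lineage.items()
        if lab in lineage_idx
    }
    table = _crosstab(cluster_of, category_of)
    res = phi_fit(table)
    return SpeciationTest(
        model="geology_lineage", table=table, chi2=res.chi2, phi=res.phi,
        p=res.p, n=res.n, degenerate=res.degenerate,
    )


# ---------------------------------------------------------------------------
# Per-transect report

@dataclass
class AnalysisConfig:
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    amova_permutations: int = 999
    geological_boundary: float | None = None
    heteroscedasticity_threshold: float = 2.5
    #: None -> decide from the climate profile via ecotone_is_real
    has_ecotone: bool | None = None
    run_qc: bool = False
    qc_permutations: int = 2000


@dataclass
class TransectReport:
    """Machine-readable per-transect summary; every statistic is traceable
    to the operation, settings and seed that produced it."""

    transect_id: str
    seed: int
    settings: dict
    lineage_frequencies: dict | None = None
    climate: dict | None = None
    ecotone: dict | None = None
    traits: dict | None = None
    correlations: dict | None = None
    qc: dict | None = None
    k_selection: dict | None = None
    cluster_site_frequencies: dict | None = None
    pca_cluster_correlation: dict | None = None
    amova_lineage: dict | None = None
    amova_habitat: dict | None = None
    fst_lineage: dict | None = None
    fst_habitat: dict | None = None
    phi_geology_lineage: dict | None = None
    phi_allopatric: dict | None = None
    phi_ecological: dict | None = None
    cv1_histogram: dict | None = None
    errors: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=_jsonable,
                          **kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _phi_dict(t: SpeciationTest) -> dict:
    return {
        "model": t.model,
        "table": [t.table.a, t.table.b, t.table.c, t.table.d],
        "chi2": t.chi2, "phi": t.phi, "p": t.p, "n": t.n,
        "k_used": t.k_used, "forced_k": t.forced_k,
        "degenerate": t.degenerate,
    }


def _amova_dict(r) -> dict:
    return {
        "sigma_among_groups": r.sigma_among_groups,
        "sigma_among_pops": r.sigma_among_pops,
        "sigma_within": r.sigma_within,
        "phi_ct": r.phi_ct, "phi_sc": r.phi_sc, "phi_st": r.phi_st,
        "p_phi_ct": r.p_phi_ct, "n_permutations": r.n_permutations,
        "grouping": r.grouping,
    }


def analyze_transect(dataset: TransectDataset, config: AnalysisConfig,
                     seed: int = 0) -> TransectReport:
    """Run the full pipeline on one transect and assemble the report.

    Stage order: lineage frequencies -> climate PCA + ecotone -> trait CVA
    + site correlations -> (optional) HWE/LD QC -> admixture clustering
    with K selection and a forced K=2 view -> allele-frequency PCA and its
    correlation with cluster frequencies -> AMOVA by lineage and (when an
    ecotone exists) habitat -> boundary F_ST' -> phi tests.  A stage error
    is recorded and its dependents skipped; a report is always produced.
    """
    rep = TransectReport(
        transect_id=dataset.transect_id,
        seed=seed,
        settings={
            "mcmc": asdict(config.mcmc),
            "amova_permutations": config.amova_permutations,
            "geological_boundary": config.geological_boundary,
            "heteroscedasticity_threshold": config.heteroscedasticity_threshold,
        },
    )
    gt = dataset.genotypes
    positions = dataset.positions
    site_ids = dataset.site_ids

    # --- mtDNA lineage frequencies
    have_lineage = bool(dataset.mtdna_lineage)
    lineage_freqs = None
    if have_lineage:
        try:
            lineage_freqs = lineage_site_frequencies(dataset)
            rep.lineage_frequencies = {
                s: {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                    for k, v in row.items()}
                for s, row in lineage_freqs.iterrows()
            }
        except Exception as e:  # noqa: BLE001 - report collects stage errors
            rep.errors["lineage_frequencies"] = str(e)
            have_lineage = False

    # --- climate + ecotone
    partition = None
    profile = None
    ecotone_present = False
    try:
        profile = climate_pca(dataset.climate_frame(), positions,
                              dataset.transect_id)
        rep.climate = {
            "component_index": profile.component_index,
            "scores": profile.scores.to_dict(),
            "proportion_variance": profile.proportion_variance,
            "magnitude": profile.magnitude,
            "r_with_position": profile.r_with_position,
        }
        partition = ecotone_partition(profile)
        ecotone_present = (
            config.has_ecotone if config.has_ecotone is not None
            else (not partition.no_ecotone and ecotone_is_real(profile))
        )
        rep.ecotone = {
            "cut_point": partition.cut_point,
            "labels": partition.labels.to_dict(),
            "boundary": list(partition.boundary) if partition.boundary else None,
            "multiple_boundaries": partition.multiple_boundaries,
            "no_ecotone": partition.no_ecotone,
            "ecotone_present": ecotone_present,
        }
    except Exception as e:  # noqa: BLE001
        rep.errors["climate"] = str(e)

    # --- traits
    cva = None
    if dataset.traits:
        try:
            pos_map = {s.site_id: s.position for s in dataset.sites}
            cva = cva_traits(
                dataset.traits, pos_map,
                heteroscedasticity_threshold=config.heteroscedasticity_threshold,
            )
            rep.traits = {
                "method": cva.method,
                "site_mean_scores": cva.site_mean_scores.to_dict(),
                "magnitude": cva.magnitude,
                "heteroscedasticity_spread": cva.heteroscedasticity_spread,
            }
            if cva.individual_scores is not None:
                hist, edges = np.histogram(
                    cva.individual_scores.to_numpy(), bins=20
                )
                rep.cv1_histogram = {
                    "counts": hist.tolist(), "bin_edges": edges.tolist()
                }
        except Exception as e:  # noqa: BLE001
            rep.errors["traits"] = str(e)

    # --- site correlations (traits vs lineage frequency; traits vs climate)
    corr = {}
    if cva is not None and lineage_freqs is not None:
        first_lineage = sorted(set(dataset.mtdna_lineage.values()))[0]
        ok = [s for s in site_ids
              if not lineage_freqs.loc[s, "empty"]
              and s in cva.site_mean_scores.index]
        if len(ok) >= 3:
            r, p, n = site_correlation(
                [cva.site_mean_scores[s] for s in ok],
                [lineage_freqs.loc[s, first_lineage] for s in ok],
            )
            corr["qt_vs_lineage"] = {"r": r, "p": p, "n": n}
    if cva is not None and profile is not None:
        shared = [s for s in site_ids if s in cva.site_mean_scores.index]
        if len(shared) >= 3:
            r, p, n = site_correlation(
                [cva.site_mean_scores[s] for s in shared],
                [profile.scores[s] for s in shared],
            )
            corr["qt_vs_climate"] = {"r": r, "p": p, "n": n}
    if corr:
        rep.correlations = corr

    # --- HWE / LD QC (off by default at transect scale)
    if config.run_qc:
        from .structure import hwe_test, ld_test
        try:
            qc = {"hwe": {}, "ld": {}}
            for s in site_ids:
                for locus in gt.loci:
                    try:
                        p, mono = hwe_test(gt, s, locus,
                                           n_perm=config.qc_permutations,
                                           seed=seed)
                        qc["hwe"][f"{s}:{locus}"] = {"p": p, "monomorphic": mono}
                    except ValueError:
                        continue
            qc["hwe_bonferroni"] = 0.05 / max(len(qc["hwe"]), 1)
            rep.qc = qc
        except Exception as e:  # noqa: BLE001
            rep.errors["qc"] = str(e)

    # --- clustering
    q2_mean = None
    cluster_of = None
    chosen_k = None
    try:
        runs = run_replicates(gt, config.mcmc, seed=seed)
        sel = select_k(runs)
        chosen_k = sel.chosen_k
        rep.k_selection = {
            "per_k": {int(k): row.to_dict() for k, row in sel.per_k.iterrows()},
            "chosen_k": sel.chosen_k, "tie": sel.tie,
        }
        if 2 in runs:
            aligned, q2_mean, _ = align_runs([e.Q for e in runs[2]])
            freqs2 = site_cluster_frequencies(gt, q2_mean, site_ids)
            rep.cluster_site_frequencies = {
                s: row.to_dict() for s, row in freqs2.iterrows()
            }
            from .structure import hard_assignments as _ha
            labels = _ha(q2_mean)
            cluster_of = dict(zip(gt.individual_ids, labels.tolist()))
    except Exception as e:  # noqa: BLE001
        rep.errors["clustering"] = str(e)

    # --- allele-frequency PCA vs cluster frequencies
    try:
        pc1 = allele_freq_pca(gt, site_ids, positions)
        if q2_mean is not None:
            freqs2 = site_cluster_frequencies(gt, q2_mean, site_ids)
            r, p, n = site_correlation(
                pc1.reindex(freqs2.index).to_numpy(),
                freqs2["cluster_1"].to_numpy(),
            )
            rep.pca_cluster_correlation = {
                "r": r, "abs_r": abs(r) if np.isfinite(r) else None,
                "p": p, "n": n, "pc1_scores": pc1.to_dict(),
            }
    except Exception as e:  # noqa: BLE001
        rep.errors["allele_freq_pca"] = str(e)

    # --- AMOVA + F_ST'
    if have_lineage and lineage_freqs is not None:
        try:
            modal = {
                s: lineage_freqs.loc[s, "mode"] for s in site_ids
                if not lineage_freqs.loc[s, "empty"]
                and not lineage_freqs.loc[s, "tie"]
            }
            if len(set(modal.values())) == 2:
                res = amova(gt, gt.site_of, modal,
                            n_perm=config.amova_permutations, seed=seed)
                res.grouping = "lineage"
                rep.amova_lineage = _amova_dict(res)
                mean_std, _ = mean_boundary_fst_std(dataset, "lineage")
                rep.fst_lineage = {"mean_fst_std": mean_std}
        except Exception as e:  # noqa: BLE001
            rep.errors["amova_lineage"] = str(e)
    if partition is not None and ecotone_present:
        try:
            habitat_of = {s: partition.labels[s] for s in site_ids}
            if len(set(habitat_of.values())) == 2:
                res = amova(gt, gt.site_of, habitat_of,
                            n_perm=config.amova_permutations, seed=seed)
                res.grouping = "habitat"
                rep.amova_habitat = _amova_dict(res)
                mean_std, _ = mean_boundary_fst_std(
                    dataset, "habitat", partition
                )
                rep.fst_habitat = {"mean_fst_std": mean_std}
        except Exception as e:  # noqa: BLE001
            rep.errors["amova_habitat"] = str(e)

    # --- phi tests
    if have_lineage and config.geological_boundary is not None:
        try:
            rep.phi_geology_lineage = _phi_dict(
                geology_lineage_fit(dataset, config.geological_boundary)
            )
        except Exception as e:  # noqa: BLE001
            rep.errors["phi_geology_lineage"] = str(e)
    if cluster_of is not None:
        forced = chosen_k != 2
        if have_lineage:
            try:
                rep.phi_allopatric = _phi_dict(test_speciation(
                    dataset, cluster_of, "allopatric",
                    k_used=2, forced_k=forced,
                ))
            except Exception as e:  # noqa: BLE001
                rep.errors["phi_allopatric"] = str(e)
        if partition is not None and ecotone_present:
            try:
                rep.phi_ecological = _phi_dict(test_speciation(
                    dataset, cluster_of, "ecological", partition=partition,
                    k_used=2, forced_k=forced,
                ))
            except Exception as e:  # noqa: BLE001
                rep.errors["phi_ecological"] = str(e)

    return rep
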